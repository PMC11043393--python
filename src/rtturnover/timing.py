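"""Replication-timing tracks: scaling, binning, domain clustering, element RT.

Replication timing (RT) is the z-scored early/late Repli-seq coverage ratio:
higher values replicate earlier in S-phase. Domains are classified per bin as
constitutively early (RT > 0.5 in every cell type), constitutively late
(RT < -0.5 in every cell type) or dynamic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.mixture import GaussianMixture

from .core import ElementSet, TrackRecord, ValidationError

EARLY_THRESHOLD = 0.5
LATE_THRESHOLD = -0.5


@dataclass
class ReplicationTrack:
    """A binned replication-timing signal for one cell type.

    ``df`` has columns chrom, start, end, value with non-overlapping sorted
    intervals.
    """

    cell_type: str
    df: pd.DataFrame

    def __post_init__(self) -> None:
        self.df = self.df.sort_values(["chrom", "start"], kind="mergesort").reset_index(
            drop=True
        )
        for chrom, sub in self.df.groupby("chrom"):
            if (sub["start"].to_numpy()[1:] < sub["end"].to_numpy()[:-1]).any():
                raise ValidationError(f"track {self.cell_type}: overlapping bins on {chrom}")

    @classmethod
    def from_records(cls, cell_type: str, records: list[TrackRecord]) -> "ReplicationTrack":
        rows = [
            (r.interval.chrom, r.interval.start, r.interval.end, r.value) for r in records
        ]
        return cls(cell_type, pd.DataFrame(rows, columns=["chrom", "start", "end", "value"]))

    def to_records(self) -> list[TrackRecord]:
        from .core import GenomicInterval

        return [
            TrackRecord(GenomicInterval(r.chrom, int(r.start), int(r.end)), float(r.value))
            for r in self.df.itertuples(index=False)
        ]

    @property
    def values(self) -> np.ndarray:
        return self.df["value"].to_numpy(dtype=float)


def zscore_track(track: ReplicationTrack) -> ReplicationTrack:
    """Center and scale a track to mean 0, population sd 1.

    Raises on constant tracks (zero variance leaves the scale undefined).
    """
    vals = track.values
    if len(vals) < 2:
        raise ValidationError("z-scoring requires at least 2 bins")
    sd = vals.std(ddof=0)
    if sd == 0:
        raise ValidationError(f"track {track.cell_type} is constant; cannot z-score")
    df = track.df.copy()
    df["value"] = (vals - vals.mean()) / sd
    return ReplicationTrack(track.cell_type, df)


def bin_mean_rt(tracks: list[ReplicationTrack], bin_size: int) -> pd.DataFrame:
    """Average tracks onto a fixed grid of ``bin_size`` bins per chromosome.

    Source records are weighted by their overlap length with each target bin.
    Bins with no data in a track are NaN (and dropped before clustering).
    Returns a DomainTable frame: chrom, start, end + one column per cell type.
    """
    chrom_ends: dict[str, int] = {}
    for track in tracks:
        for chrom, sub in track.df.groupby("chrom"):
            chrom_ends[chrom] = max(chrom_ends.get(chrom, 0), int(sub["end"].max()))
    rows = []
    for chrom in sorted(chrom_ends):
        n_bins = math.ceil(chrom_ends[chrom] / bin_size)
        for i in range(n_bins):
            rows.append((chrom, i * bin_size, (i + 1) * bin_size))
    domain = pd.DataFrame(rows, columns=["chrom", "start", "end"])

    index = {(c, s): i for i, (c, s) in enumerate(zip(domain["chrom"], domain["start"]))}
    for track in tracks:
        sums = np.zeros(len(domain))
        weights = np.zeros(len(domain))
        for rec in track.df.itertuples(index=False):
            first = rec.start // bin_size
            last = (rec.end - 1) // bin_size
            for b in range(first, last + 1):
                bs, be = b * bin_size, (b + 1) * bin_size
                ov = min(be, rec.end) - max(bs, rec.start)
                if ov > 0:
                    i = index[(rec.chrom, bs)]
                    sums[i] += ov * rec.value
                    weights[i] += ov
        with np.errstate(invalid="ignore"):
            domain[track.cell_type] = np.where(weights > 0, sums / np.maximum(weights, 1), np.nan)
    return domain


def celltype_columns(domain: pd.DataFrame) -> list[str]:
    reserved = {"chrom", "start", "end", "cluster", "rt_class"}
    return [c for c in domain.columns if c not in reserved]


def cluster_bins(
    domain: pd.DataFrame,
    k_max: int = 20,
    seed: int = 0,
    n_restarts: int = 10,
) -> pd.DataFrame:
    """Cluster bins on the bin x cell-type RT matrix.

    The number of clusters is chosen by Gaussian-mixture BIC over 1..k_max,
    then k-means with that k assigns clusters. Cluster ids are contiguous from
    1 and ordered from earliest (highest mean RT) to latest.
    """
    if k_max < 2:
        raise ValidationError("k_max must be >= 2")
    cols = celltype_columns(domain)
    X = domain[cols].to_numpy(dtype=float)
    ok = ~np.isnan(X).any(axis=1)
    Xc = X[ok]
    if len(Xc) < k_max:
        raise ValidationError(f"need at least k_max={k_max} complete bins, got {len(Xc)}")

    best_k, best_bic = 1, np.inf
    for k in range(1, k_max + 1):
        gm = GaussianMixture(n_components=k, random_state=seed, n_init=1)
        gm.fit(Xc)
        bic = gm.bic(Xc)
        if bic < best_bic - 1e-9:
            best_bic, best_k = bic, k

    if best_k == 1:
        labels = np.zeros(len(Xc), dtype=int)
    else:
        km = KMeans(n_clusters=best_k, n_init=n_restarts, random_state=seed)
        labels = km.fit_predict(Xc)

    # order clusters from earliest (highest mean RT) to latest
    mean_rt = Xc.mean(axis=1)
    order = np.argsort(
        [-mean_rt[labels == c].mean() for c in range(best_k)], kind="stable"
    )
    remap = np.empty(best_k, dtype=int)
    remap[order] = np.arange(1, best_k + 1)

    out = domain.copy()
    cluster = np.full(len(domain), np.nan)
    cluster[ok] = remap[labels]
    out["cluster"] = cluster
    return out


def classify_constitutive(
    domain: pd.DataFrame,
    early_thr: float = EARLY_THRESHOLD,
    late_thr: float = LATE_THRESHOLD,
) -> pd.DataFrame:
    """Label each bin early/late/dynamic from per-cell-type RT.

    Early requires RT strictly above ``early_thr`` in every cell type; late
    requires RT strictly below ``late_thr`` in every cell type; anything else
    (including values exactly at a threshold) is dynamic.
    """
    cols = celltype_columns(domain)
    X = domain[cols].to_numpy(dtype=float)
    complete = ~np.isnan(X).any(axis=1)
    early = complete & (X > early_thr).all(axis=1)
    late = complete & (X < late_thr).all(axis=1)
    out = domain.copy()
    rt_class = np.where(early, "early", np.where(late, "late", "dynamic"))
    rt_class = np.where(complete, rt_class, "missing")
    out["rt_class"] = rt_class
    return out


def assign_element_rt(
    elements: ElementSet, track: ReplicationTrack, weighted: bool = False
) -> ElementSet:
    """Attach per-element RT as the mean of all overlapped track bins.

    The default is the unweighted mean over overlapped bins (overlap length is
    ignored); ``weighted=True`` switches to an overlap-length-weighted mean.
    Elements overlapping no bin get NaN.
    """
    rt = np.full(len(elements), np.nan)
    by_chrom = {}
    for chrom, sub in track.df.groupby("chrom"):
        by_chrom[chrom] = (
            sub["start"].to_numpy(),
            sub["end"].to_numpy(),
            sub["value"].to_numpy(dtype=float),
        )
    for idx, row in enumerate(elements.df.itertuples(index=False)):
        got = by_chrom.get(row.chrom)
        if got is None:
            continue
        starts, ends, vals = got
        lo = np.searchsorted(ends, row.start, side="right")
        hi = np.searchsorted(starts, row.end, side="left")
        if hi <= lo:
            continue
        if weighted:
            ov = np.minimum(ends[lo:hi], row.end) - np.maximum(starts[lo:hi], row.start)
            ov = np.maximum(ov, 0)
            if ov.sum() > 0:
                rt[idx] = float(np.average(vals[lo:hi], weights=ov))
        else:
            rt[idx] = float(vals[lo:hi].mean())
    return elements.with_column("rt", rt)


def classify_element_rt(
    elements: ElementSet,
    early_thr: float = EARLY_THRESHOLD,
    late_thr: float = LATE_THRESHOLD,
) -> ElementSet:
    """Label elements early/late/dynamic by their (mean) RT value."""
    rt = elements.df["rt"].to_numpy(dtype=float)
    cls = np.where(rt > early_thr, "early", np.where(rt < late_thr, "late", "dynamic"))
    cls = np.where(np.isnan(rt), "missing", cls)
    return elements.with_column("rt_class", cls)


def rt_quintiles(elements: ElementSet, latest_first: bool = True) -> ElementSet:
    """Split elements into 5 RT quintiles of near-equal size.

    By default quintile 1 is the latest-replicating fifth and quintile 5 the
    earliest (``latest_first=False`` reverses the labels). Ties are broken by
    (chrom, start) so the split is deterministic. Elements with missing RT are
    left unlabeled (quintile 0).
    """
    df = elements.df
    rt = df["rt"].to_numpy(dtype=float)
    valid = np.flatnonzero(~np.isnan(rt))
    if len(valid) < 5:
        raise ValidationError("need at least 5 elements with non-missing RT")
    order = df.iloc[valid].sort_values(
        ["rt", "chrom", "start"], kind="mergesort"
    ).index.to_numpy()
    quint = np.zeros(len(df), dtype=int)
    for q, chunk in enumerate(np.array_split(order, 5), start=1):
        quint[chunk] = q if latest_first else 6 - q
    labels = {0: "NA"}
    for q in range(1, 6):
        tag = "latest" if (q == 1) == latest_first else ("earliest" if q in (1, 5) else "")
        labels[q] = f"Q{q} ({tag})" if q in (1, 5) else f"Q{q}"
    out = elements.with_column("rt_quintile", quint)
    return out.with_column("rt_quintile_label", [labels[q] for q in quint])


def mean_track(tracks: list[ReplicationTrack], cell_type: str = "mean") -> ReplicationTrack:
    """Per-bin arithmetic mean of tracks sharing a bin grid (NaN propagates)."""
    ref = tracks[0].df
    for t in tracks[1:]:
        if len(t.df) != len(ref) or not (
            (t.df["chrom"].to_numpy() == ref["chrom"].to_numpy()).all()
            and (t.df["start"].to_numpy() == ref["start"].to_numpy()).all()
        ):
            raise ValidationError("tracks must share an identical bin grid")
    vals = np.stack([t.values for t in tracks])
    df = ref[["chrom", "start", "end"]].copy()
    df["value"] = vals.mean(axis=0)
    return ReplicationTrack(cell_type, df)


# the paper's germline RT is the mean over the four germline assays (2 PGC + 2 SSC)
mean_germline_rt = mean_track
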