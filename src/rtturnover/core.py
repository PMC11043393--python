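"""Core domain types shared across the package.

All coordinates are 0-based, half-open (BED-native). Inputs that use 1-based
conventions (VCF positions, PFM columns) are converted at the I/O boundary and
nowhere else.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

STRANDS = ("+", "-", ".")

_SEX_CHROM_RE = re.compile(r"^(chr)?(x|y|w|z|m|mt)$", re.IGNORECASE)


class ParseError(ValueError):
    """Raised when an input file cannot be parsed; names the offending line."""


class ValidationError(ValueError):
    """Raised when parsed input violates a domain invariant."""


@dataclass
class GenomicInterval:
    """A genomic interval in 0-based half-open coordinates."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    attributes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValidationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class TrackRecord:
    """One binned signal value (e.g. replication timing) on an interval."""

    interval: GenomicInterval
    value: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.value):
            raise ValidationError(
                f"non-finite track value at "
                f"{self.interval.chrom}:{self.interval.start}-{self.interval.end}"
            )


class ElementSet:
    """A set of genomic elements with arbitrary per-element attributes.

    Backed by a :class:`pandas.DataFrame` with mandatory columns
    ``chrom``, ``start``, ``end`` (0-based half-open) plus any number of
    attribute columns (``id``, ``age``, ``rt``, ``rt_quintile``, ``fate``, ...).
    Rows are kept sorted by (chrom, start, end).
    """

    REQUIRED = ("chrom", "start", "end")

    def __init__(self, df: pd.DataFrame, validate: bool = True):
        df = df.reset_index(drop=True)
        for col in self.REQUIRED:
            if col not in df.columns:
                raise ValidationError(f"ElementSet requires column {col!r}")
        if validate and len(df):
            starts = df["start"].to_numpy()
            ends = df["end"].to_numpy()
            if (starts < 0).any() or (starts >= ends).any():
                raise ValidationError("ElementSet requires 0 <= start < end")
        if "strand" not in df.columns:
            df = df.assign(strand=".")
        self.df = df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(
            drop=True
        )

    # -- construction -------------------------------------------------------
    @classmethod
    def from_intervals(cls, intervals: Iterable[GenomicInterval]) -> "ElementSet":
        rows = []
        for iv in intervals:
            row = {"chrom": iv.chrom, "start": iv.start, "end": iv.end, "strand": iv.strand}
            row.update(iv.attributes)
            rows.append(row)
        if not rows:
            return cls(pd.DataFrame(columns=list(cls.REQUIRED)), validate=False)
        return cls(pd.DataFrame(rows))

    def to_intervals(self) -> list[GenomicInterval]:
        out = []
        extra = [c for c in self.df.columns if c not in ("chrom", "start", "end", "strand")]
        for row in self.df.itertuples(index=False):
            attrs = {c: getattr(row, c) for c in extra}
            out.append(
                GenomicInterval(row.chrom, int(row.start), int(row.end), row.strand, attrs)
            )
        return out

    # -- basic protocol -----------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    @property
    def lengths(self) -> np.ndarray:
        return (self.df["end"] - self.df["start"]).to_numpy()

    def with_column(self, name: str, values) -> "ElementSet":
        df = self.df.copy()
        df[name] = values
        return ElementSet(df, validate=False)

    def subset(self, mask) -> "ElementSet":
        return ElementSet(self.df.loc[np.asarray(mask)], validate=False)

    def autosomes(self) -> "ElementSet":
        keep = ~self.df["chrom"].map(lambda c: bool(_SEX_CHROM_RE.match(str(c))))
        return self.subset(keep.to_numpy())


class VariantTable:
    """Positioned variants with derived-allele frequencies.

    Backed by a DataFrame with columns ``chrom``, ``pos`` (0-based) and ``daf``
    in [0, 1]; an optional ``daf_class`` column holds the rare/common/excluded
    classification.
    """

    def __init__(self, df: pd.DataFrame, validate: bool = True):
        for col in ("chrom", "pos", "daf"):
            if col not in df.columns:
                raise ValidationError(f"VariantTable requires column {col!r}")
        if validate and len(df):
            daf = df["daf"].to_numpy(dtype=float)
            if ((daf < 0) | (daf > 1)).any():
                bad = df.loc[(daf < 0) | (daf > 1)].iloc[0]
                raise ValidationError(
                    f"DAF outside [0,1] at {bad['chrom']}:{bad['pos']}: {bad['daf']}"
                )
        self.df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class MarkMatrix:
    """Element x species binary table of enhancer-associated mark presence.

    The focal species is the first column and must be all-present: every row is
    an enhancer in the focal species by construction.
    """

    element_ids: list[str]
    species: list[str]
    present: np.ndarray  # bool, shape (n_elements, n_species)

    def __post_init__(self) -> None:
        self.present = np.asarray(self.present, dtype=bool)
        if self.present.shape != (len(self.element_ids), len(self.species)):
            raise ValidationError("MarkMatrix shape does not match ids/species")
        if len(self.species) and not self.present[:, 0].all():
            raise ValidationError("focal species column must be all-present")

    def n_other_species(self) -> np.ndarray:
        """Per element, number of non-focal species with the mark."""
        return self.present[:, 1:].sum(axis=1)


@dataclass
class PositionWeightMatrix:
    """Per-position nucleotide frequencies of a TF binding motif (A,C,G,T)."""

    id: str
    name: str
    freqs: np.ndarray  # shape (length, 4), rows sum to 1

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.freqs.ndim != 2 or self.freqs.shape[1] != 4:
            raise ValidationError(f"PWM {self.id}: frequency matrix must be L x 4")
        if (self.freqs < 0).any():
            raise ValidationError(f"PWM {self.id}: negative frequencies")
        sums = self.freqs.sum(axis=1)
        if np.abs(sums - 1.0).max() > 1e-9:
            raise ValidationError(f"PWM {self.id}: columns do not sum to 1")

    @property
    def length(self) -> int:
        return self.freqs.shape[0]


@dataclass
class HomologyHit:
    """A pairwise sequence-similarity hit (tabular BLAST dialect)."""

    query: str
    subject: str
    e_value: float
    query_coverage: float  # percent of query length

    def __post_init__(self) -> None:
        if self.e_value < 0:
            raise ValidationError(f"negative E-value for {self.query}/{self.subject}")
        if not (0 <= self.query_coverage <= 100):
            raise ValidationError(
                f"query coverage {self.query_coverage} outside [0,100] "
                f"for {self.query}/{self.subject}"
            )


@dataclass
class MixtureFit:
    """A 2-component univariate Gaussian mixture fit (components mu-ascending)."""

    mu: tuple[float, float]
    sigma: tuple[float, float]
    lam: tuple[float, float]
    loglik: float
    n_iter: int
    loglik_trace: np.ndarray = field(default_factory=lambda: np.empty(0))


# ---------------------------------------------------------------------------
# interval arithmetic helpers


def merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping/adjacent intervals; returns sorted chrom/start/end."""
    out = []
    for chrom, sub in df.sort_values(["chrom", "start"]).groupby("chrom", sort=True):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        cur_s, cur_e = starts[0], ends[0]
        for s, e in zip(starts[1:], ends[1:]):
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append((chrom, cur_s, cur_e))
    return pd.DataFrame(out, columns=["chrom", "start", "end"])


def overlap_with_set(elements: ElementSet, other: ElementSet) -> np.ndarray:
    """Total bp of each element covered by the union footprint of ``other``."""
    if len(other) == 0:
        return np.zeros(len(elements), dtype=int)
    merged = merge_intervals(other.df[["chrom", "start", "end"]])
    cov = np.zeros(len(elements), dtype=int)
    by_chrom = {c: g for c, g in merged.groupby("chrom")}
    for idx, row in enumerate(elements.df.itertuples(index=False)):
        sub = by_chrom.get(row.chrom)
        if sub is None:
            continue
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        lo = np.searchsorted(ends, row.start, side="right")
        hi = np.searchsorted(starts, row.end, side="left")
        if hi > lo:
            ov = np.minimum(ends[lo:hi], row.end) - np.maximum(starts[lo:hi], row.start)
            cov[idx] = int(ov[ov > 0].sum())
    return cov


def count_points_in_elements(elements: ElementSet, points: pd.DataFrame) -> np.ndarray:
    """Count positions (columns chrom/pos) falling inside each element."""
    counts = np.zeros(len(elements), dtype=int)
    if not len(points):
        return counts
    by_chrom = {c: np.sort(g["pos"].to_numpy()) for c, g in points.groupby("chrom")}
    for idx, row in enumerate(elements.df.itertuples(index=False)):
        pos = by_chrom.get(row.chrom)
        if pos is None:
            continue
        counts[idx] = int(
            np.searchsorted(pos, row.end, side="left")
            - np.searchsorted(pos, row.start, side="left")
        )
    return counts
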