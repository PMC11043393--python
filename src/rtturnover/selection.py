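"""Derived-allele-frequency (DAF) selection scan.

Variants are dichotomized into rare (DAF < 1.5%) and common (DAF > 5%)
classes; intermediate frequencies are excluded. Around a set of motif centers
the rare and common counts are pooled into 10 bp offset windows, normalized by
the mean rates in the 2-4 kb flanks, and summarized as rare-vs-common odds
ratios; an excess of rare alleles (OR > 1) over the flanks indicates
purifying selection at the motif positions. Confidence bands come from
bootstrap resampling of the motif centers.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .core import ElementSet, ValidationError, VariantTable
from .stats import exact_or_confint, fisher_exact_or, sample_odds_ratio

RARE_MAX_DAF = 0.015  # strict <
COMMON_MIN_DAF = 0.05  # strict >
FLANK_BP = (2000, 4000)  # flank normalization uses [-4000,-2000) u [2000,4000)


def classify_daf(
    variants: VariantTable,
    rare_max: float = RARE_MAX_DAF,
    common_min: float = COMMON_MIN_DAF,
) -> VariantTable:
    """Assign rare/common/excluded classes by strict DAF thresholds."""
    df = variants.df.copy()
    daf = df["daf"].to_numpy(dtype=float)
    df["daf_class"] = np.where(
        daf < rare_max, "rare", np.where(daf > common_min, "common", "excluded")
    )
    return VariantTable(df, validate=False)


def _centers_frame(centers) -> pd.DataFrame:
    if isinstance(centers, pd.DataFrame):
        return centers[["chrom", "pos"]]
    return pd.DataFrame(centers, columns=["chrom", "pos"])


def profile_counts_per_center(
    variants: VariantTable, centers, window: int = 10, reach: int = FLANK_BP[1]
) -> tuple[np.ndarray, np.ndarray]:
    """Rare/common counts per (center, offset window).

    Offset windows use floor division: window 0 covers [center, center+window).
    Returns (counts with shape (n_centers, n_windows, 2) for rare/common,
    offset_bp array of window left edges). Variants within several centers'
    reach are counted once per center (pooled, stack-and-sum convention).
    """
    if reach % window:
        raise ValidationError("reach must be a multiple of the window size")
    cdf = _centers_frame(centers).reset_index(drop=True)
    if not len(cdf):
        raise ValidationError("need at least 1 center")
    n_win = 2 * reach // window
    offsets = (np.arange(n_win) - n_win // 2) * window
    counts = np.zeros((len(cdf), n_win, 2), dtype=np.int64)
    df = variants.df
    if "daf_class" not in df.columns:
        df = classify_daf(variants).df
    df = df[df["daf_class"].isin(["rare", "common"])]
    var_by_chrom = {
        c: (g["pos"].to_numpy(), (g["daf_class"] == "common").to_numpy().astype(int))
        for c, g in df.groupby("chrom")
    }
    for ci, crow in enumerate(cdf.itertuples(index=False)):
        got = var_by_chrom.get(crow.chrom)
        if got is None:
            continue
        pos, cls = got
        lo = np.searchsorted(pos, crow.pos - reach, side="left")
        hi = np.searchsorted(pos, crow.pos + reach, side="left")
        if hi <= lo:
            continue
        widx = (pos[lo:hi] - crow.pos) // window + n_win // 2
        np.add.at(counts, (ci, widx, cls[lo:hi]), 1)
    return counts, offsets


def _profile_from_counts(
    counts_sum: np.ndarray, offsets: np.ndarray, n_centers: int, span: int
) -> pd.DataFrame:
    flank = (np.abs(offsets) >= FLANK_BP[0]) & (np.abs(offsets) < FLANK_BP[1])
    n_rare = counts_sum[:, 0].astype(float)
    n_common = counts_sum[:, 1].astype(float)
    rate_rare = n_rare / n_centers
    rate_common = n_common / n_centers
    flank_rare = rate_rare[flank].mean()
    flank_common = rate_common[flank].mean()
    with np.errstate(divide="ignore", invalid="ignore"):
        norm_rare = np.where(flank_rare > 0, rate_rare / flank_rare, np.nan)
        norm_common = np.where(flank_common > 0, rate_common / flank_common, np.nan)
    fr, fc = n_rare[flank].sum(), n_common[flank].sum()
    ors = np.array(
        [
            sample_odds_ratio(np.array([[r, c], [fr, fc]]))
            for r, c in zip(n_rare, n_common)
        ]
    )
    return pd.DataFrame(
        {
            "offset_bp": offsets,
            "n_rare": n_rare.astype(int),
            "n_common": n_common.astype(int),
            "rate_rare_norm": norm_rare,
            "rate_common_norm": norm_common,
            "odds_ratio": ors,
            "in_flank": flank,
            "in_span": np.abs(offsets) < span,
        }
    )


def motif_centered_profile(
    variants: VariantTable, centers, span: int = 2000, window: int = 10
) -> pd.DataFrame:
    """Pooled rare/common DAF profile in offset windows around motif centers.

    Counts are summed over centers; per-window rates are normalized by the
    mean rate over the 2-4 kb flanks on both sides, and each window's
    rare-vs-common odds ratio is taken against the pooled flank counts.
    """
    reach = max(span, FLANK_BP[1])
    if span > FLANK_BP[0]:
        warnings.warn(
            f"span {span} bp reaches into the {FLANK_BP[0]}-{FLANK_BP[1]} bp "
            "normalization flanks",
            RuntimeWarning,
            stacklevel=2,
        )
    counts, offsets = profile_counts_per_center(variants, centers, window, reach)
    return _profile_from_counts(counts.sum(axis=0), offsets, counts.shape[0], span)


def daf_odds_ratio(
    focal: tuple[int, int], background: tuple[int, int], alpha: float = 0.05
) -> dict:
    """Odds ratio of rare vs common alleles, focal against background.

    OR = (rare_f/common_f)/(rare_b/common_b); the p value and confidence
    interval come from Fisher's exact test (exact conditional CI). Tables with
    a zero focal cell report OR as NA with a one-sided note.
    """
    table = np.array([list(focal), list(background)], dtype=int)
    res = fisher_exact_or(table, alternative="two-sided")
    ci_low, ci_high = exact_or_confint(table, alpha=alpha)
    note = ""
    if not np.isfinite(res["odds_ratio"]):
        note = "zero cell: odds ratio undefined; interpret one-sidedly"
        res["odds_ratio"] = np.nan
    return {
        "or": res["odds_ratio"],
        "ci_low": ci_low,
        "ci_high": ci_high,
        "p": res["p"],
        "note": note,
    }


def bootstrap_profile(
    variants: VariantTable,
    centers,
    n_boot: int = 100,
    seed: int = 0,
    span: int = 2000,
    window: int = 10,
) -> pd.DataFrame:
    """Profile with 95% bootstrap bands from resampling centers with replacement.

    Per window, ci_low/ci_high are the 2.5/97.5 percentiles of the odds ratio
    over ``n_boot`` resampled profiles.
    """
    reach = max(span, FLANK_BP[1])
    counts, offsets = profile_counts_per_center(variants, centers, window, reach)
    n_centers = counts.shape[0]
    profile = _profile_from_counts(counts.sum(axis=0), offsets, n_centers, span)
    rng = np.random.default_rng(seed)
    flank = profile["in_flank"].to_numpy()
    boot_or = np.empty((n_boot, len(offsets)))
    for b in range(n_boot):
        idx = rng.integers(0, n_centers, size=n_centers)
        cs = counts[idx].sum(axis=0).astype(float)
        fr, fc = cs[flank, 0].sum(), cs[flank, 1].sum()
        with np.errstate(divide="ignore", invalid="ignore"):
            boot_or[b] = (cs[:, 0] * fc) / (cs[:, 1] * fr)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        lo = np.nanpercentile(boot_or, 2.5, axis=0)
        hi = np.nanpercentile(boot_or, 97.5, axis=0)
    profile["ci_low"] = lo
    profile["ci_high"] = hi
    return profile


def sample_matched_background(
    elements: ElementSet,
    universe: ElementSet,
    n: int,
    seed: int = 0,
    autosome_only: bool = True,
    max_tries_per_region: int = 200,
) -> ElementSet:
    """Random non-overlapping background regions length-matched to ``elements``.

    Region lengths are drawn from the focal length distribution; placements
    are uniform within the allowed universe, rejecting overlaps with already
    placed regions. Sex chromosomes are excluded when recognizable by name.
    """
    if autosome_only:
        universe = universe.autosomes()
    udf = universe.df
    if not len(udf):
        raise ValidationError("empty universe after filtering")
    lengths = elements.lengths
    rng = np.random.default_rng(seed)
    placed: dict[str, list[tuple[int, int]]] = {}
    rows = []
    ulens = udf["end"].to_numpy() - udf["start"].to_numpy()
    for _ in range(n):
        length = int(lengths[rng.integers(0, len(lengths))])
        ok = False
        for _try in range(max_tries_per_region):
            avail = np.maximum(ulens - length + 1, 0)
            if avail.sum() == 0:
                break
            ui = rng.choice(len(udf), p=avail / avail.sum())
            urow = udf.iloc[ui]
            start = int(urow["start"] + rng.integers(0, avail[ui]))
            end = start + length
            prior = placed.setdefault(urow["chrom"], [])
            if any(s < end and start < e for s, e in prior):
                continue
            prior.append((start, end))
            rows.append((urow["chrom"], start, end))
            ok = True
            break
        if not ok:
            raise ValidationError(
                "could not place background regions without overlap; "
                "universe too small for the requested n"
            )
    return ElementSet(pd.DataFrame(rows, columns=["chrom", "start", "end"]))
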