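"""Enhancer age classification and turnover statistics.

An enhancer is "conserved" when enhancer-associated histone marks co-occur at
aligned regions in at least two other species, otherwise "recent"
(lineage-specific). Turnover per genomic group (replication-time cluster or
quintile) is the log ratio of recent to conserved counts; its regression on
mean replication time quantifies how strongly enhancer birth tracks
replication lateness. The same machinery classifies healthy/tumor peak sets
into gained/lost/unchanged enhancers and their somatic mutation burden.
"""

from __future__ import annotations

import math
import warnings

import networkx as nx
import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .core import (
    ElementSet,
    HomologyHit,
    MarkMatrix,
    ValidationError,
    VariantTable,
    count_points_in_elements,
    merge_intervals,
    overlap_with_set,
)
from .stats import fisher_exact_or

EVALUE_CUTOFF = 1e-6  # strict <
QCOV_CUTOFF = 20.0  # strict >, percent of query length


def consensus_peaks(
    replicates: list[ElementSet], min_frac: float = 0.5, min_replicates: int = 2
) -> ElementSet:
    """Consensus peaks supported by multiple biological replicates.

    Candidate intervals are the merged union across all replicates; a
    candidate is retained iff at least ``min_replicates`` replicates each
    cover >= ``min_frac`` of its length. The reported footprint is the union
    of the supporting replicates' peaks clipped to the candidate.
    """
    if len(replicates) < 2:
        raise ValidationError("consensus_peaks requires at least 2 replicate sets")
    all_df = pd.concat([r.df[["chrom", "start", "end"]] for r in replicates])
    if not len(all_df):
        return ElementSet(pd.DataFrame(columns=["chrom", "start", "end"]), validate=False)
    candidates = ElementSet(merge_intervals(all_df), validate=False)
    cov = np.stack([overlap_with_set(candidates, rep) for rep in replicates])
    lengths = candidates.lengths
    support = cov >= np.ceil(min_frac * lengths)[None, :]
    keep = support.sum(axis=0) >= min_replicates
    rows = []
    for idx in np.flatnonzero(keep):
        cand = candidates.df.iloc[idx]
        supporting = pd.concat(
            [
                rep.df[
                    (rep.df["chrom"] == cand["chrom"])
                    & (rep.df["start"] < cand["end"])
                    & (rep.df["end"] > cand["start"])
                ][["chrom", "start", "end"]]
                for r_i, rep in enumerate(replicates)
                if support[r_i, idx]
            ]
        )
        for piece in merge_intervals(supporting).itertuples(index=False):
            rows.append(
                (
                    piece.chrom,
                    max(piece.start, cand["start"]),
                    min(piece.end, cand["end"]),
                )
            )
    return ElementSet(pd.DataFrame(rows, columns=["chrom", "start", "end"]), validate=False)


def classify_age(marks: MarkMatrix, min_other_species: int = 2) -> pd.Series:
    """Per-element age: conserved iff the mark is present in at least
    ``min_other_species`` non-focal species, else recent."""
    conserved = marks.n_other_species() >= min_other_species
    return pd.Series(
        np.where(conserved, "conserved", "recent"), index=marks.element_ids, name="age"
    )


def turnover_by_group(
    elements: ElementSet,
    group_col: str = "rt_quintile",
    log_base: float = math.e,
    pseudocount: float = 0.0,
) -> pd.DataFrame:
    """Per-group recent/conserved counts and turnover log ratio.

    log_ratio = log(n_recent / n_conserved); groups with a zero count get NaN
    unless a pseudocount alpha > 0 is supplied. Per-group mean RT is included
    when the elements carry an ``rt`` column.
    """
    df = elements.df
    rows = []
    for group, sub in df.groupby(group_col, sort=True):
        n_recent = int((sub["age"] == "recent").sum())
        n_conserved = int((sub["age"] == "conserved").sum())
        if pseudocount > 0 or (n_recent > 0 and n_conserved > 0):
            ratio = (n_recent + pseudocount) / (n_conserved + pseudocount)
            log_ratio = math.log(ratio, log_base)
        else:
            warnings.warn(
                f"group {group!r} has a zero age count; log_ratio is NA",
                RuntimeWarning,
                stacklevel=2,
            )
            log_ratio = np.nan
        mean_rt = float(sub["rt"].mean()) if "rt" in sub.columns else np.nan
        rows.append((group, n_recent, n_conserved, log_ratio, mean_rt))
    return pd.DataFrame(
        rows, columns=["group", "n_recent", "n_conserved", "log_ratio", "mean_rt"]
    )


def recent_probability_ratio(elements: ElementSet) -> float:
    """P(recent | late RT) / P(recent | early RT).

    Elements must carry ``age`` and ``rt_class`` columns; both the early and
    the late class must be non-empty.
    """
    df = elements.df
    out = {}
    for cls in ("late", "early"):
        sub = df[df["rt_class"] == cls]
        if not len(sub):
            raise ValidationError(f"no elements in the {cls} replication-time class")
        out[cls] = (sub["age"] == "recent").mean()
    if out["early"] == 0:
        raise ValidationError("P(recent | early) is 0; ratio undefined")
    return float(out["late"] / out["early"])


def regress_turnover_rt(table: pd.DataFrame) -> dict[str, float]:
    """OLS of turnover log_ratio on mean RT across groups.

    Returns slope, intercept, r_squared (squared Pearson r) and the two-sided
    p value of the correlation (t distribution, n-2 df).
    """
    sub = table.dropna(subset=["log_ratio", "mean_rt"])
    if len(sub) < 3:
        raise ValidationError("need >=3 groups with finite log_ratio and mean_rt")
    res = stats.linregress(sub["mean_rt"], sub["log_ratio"])
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r_squared": float(res.rvalue**2),
        "p_two_sided": float(res.pvalue),
    }


def tissue_interaction_test(table: pd.DataFrame) -> dict[str, float]:
    """Test whether turnover-vs-RT slopes differ between two tissue groups.

    Fits log_ratio ~ mean_rt + tissue_pair + tissue_pair:mean_rt by least
    squares, where tissue_pair is a binary group label, and reports the t
    statistic and two-sided p of the interaction coefficient.
    """
    sub = table.dropna(subset=["log_ratio", "mean_rt", "tissue_pair"])
    distinct = sub[["mean_rt", "tissue_pair"]].drop_duplicates()
    if len(sub) < 5 or len(distinct) < 4:
        raise ValidationError("interaction model unidentifiable: too few points")
    y = sub["log_ratio"].to_numpy(dtype=float)
    rt = sub["mean_rt"].to_numpy(dtype=float)
    pair = sub["tissue_pair"].to_numpy(dtype=float)
    X = sm.add_constant(np.column_stack([rt, pair, rt * pair]))
    fit = sm.OLS(y, X).fit()
    return {"interaction_t": float(fit.tvalues[3]), "p": float(fit.pvalues[3])}


def interval_enrichment(
    set_a: ElementSet,
    labels_a: np.ndarray,
    set_b: ElementSet,
    min_overlap_frac: float = 0.0,
    alternative: str = "two-sided",
) -> dict[str, float]:
    """Fisher's exact test of label vs overlap-with-B among elements of A.

    An element overlaps when >= ``min_overlap_frac`` of its base pairs are
    covered by the union footprint of B (any overlap when the fraction is 0).
    Used for TE overlap of recent vs ancestral elements, eQTL enrichment, and
    accessibility overlap (min_overlap_frac=0.3, alternative='greater').
    """
    labels_a = np.asarray(labels_a, dtype=bool)
    if len(labels_a) != len(set_a):
        raise ValidationError("labels length does not match element set")
    cov = overlap_with_set(set_a, set_b)
    if min_overlap_frac > 0:
        hits = cov >= np.ceil(min_overlap_frac * set_a.lengths)
    else:
        hits = cov > 0
    table = np.array(
        [
            [int((labels_a & hits).sum()), int((labels_a & ~hits).sum())],
            [int((~labels_a & hits).sum()), int((~labels_a & ~hits).sum())],
        ]
    )
    res = fisher_exact_or(table, alternative=alternative)
    if not np.isfinite(res["odds_ratio"]):
        warnings.warn(
            "degenerate 2x2 table: odds ratio undefined (reported as NA)",
            RuntimeWarning,
            stacklevel=2,
        )
        res["odds_ratio"] = np.nan
    res["table"] = table
    return res


def singleton_analysis(
    hits: list[HomologyHit],
    all_ids: list[str],
    evalue_cutoff: float = EVALUE_CUTOFF,
    qcov_cutoff: float = QCOV_CUTOFF,
) -> dict:
    """Singleton fraction among elements from pairwise homology hits.

    Hits are kept when E-value < cutoff (strict) and query coverage > cutoff
    (strict, percent); self-hits are dropped. Elements in no surviving hit are
    singletons (no evidence of recent duplication).
    """
    graph = nx.Graph()
    graph.add_nodes_from(all_ids)
    known = set(all_ids)
    for hit in hits:
        if hit.query == hit.subject:
            continue
        if hit.e_value < evalue_cutoff and hit.query_coverage > qcov_cutoff:
            if hit.query in known and hit.subject in known:
                graph.add_edge(hit.query, hit.subject)
    components = [set(c) for c in nx.connected_components(graph)]
    n_singletons = sum(1 for c in components if len(c) == 1)
    return {
        "singleton_fraction": n_singletons / len(all_ids) if all_ids else np.nan,
        "n_singletons": n_singletons,
        "components": components,
    }


def expected_substitutions_per_kb(
    divergence_myr: float, generation_years: float, mu_per_base_per_gen: float
) -> float:
    """Expected substitutions per kb along one lineage since a species split.

    generations since split = divergence_myr * 1e6 / generation_years;
    each generation contributes mu substitutions per base, scaled to 1 kb.
    """
    generations = divergence_myr * 1e6 / generation_years
    return generations * mu_per_base_per_gen * 1000.0


def classify_cancer_turnover(
    healthy: ElementSet, tumor: ElementSet, min_overlap_frac: float = 0.5
) -> ElementSet:
    """Label enhancers gained/lost/unchanged between healthy and tumor states.

    A tumor peak reciprocally overlapping a healthy peak by at least
    ``min_overlap_frac`` of the shorter of the two is "unchanged" (reported
    once, with the tumor coordinates); tumor-only peaks are "gained" and
    healthy-only peaks "lost".
    """
    t_matched = np.zeros(len(tumor), dtype=bool)
    h_matched = np.zeros(len(healthy), dtype=bool)
    h_by_chrom = {c: g for c, g in healthy.df.reset_index().groupby("chrom")}
    for t_idx, trow in enumerate(tumor.df.itertuples(index=False)):
        sub = h_by_chrom.get(trow.chrom)
        if sub is None:
            continue
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        lo = np.searchsorted(ends, trow.start, side="right")
        hi = np.searchsorted(starts, trow.end, side="left")
        for j in range(lo, hi):
            ov = min(ends[j], trow.end) - max(starts[j], trow.start)
            shorter = min(ends[j] - starts[j], trow.end - trow.start)
            if ov >= min_overlap_frac * shorter and ov > 0:
                t_matched[t_idx] = True
                h_matched[sub["index"].to_numpy()[j]] = True
    t_df = tumor.df.copy()
    t_df["fate"] = np.where(t_matched, "unchanged", "gained")
    t_df["state"] = "tumor"
    h_df = healthy.df.loc[~h_matched].copy()
    h_df["fate"] = "lost"
    h_df["state"] = "healthy"
    return ElementSet(pd.concat([t_df, h_df], ignore_index=True), validate=False)


def mutation_burden(
    elements: ElementSet, somatic: VariantTable, log_epsilon: float | None = None
) -> ElementSet:
    """Somatic mutation burden per element: variant count / element width (per bp).

    When ``log_epsilon`` is given a log10(burden + epsilon) column is added
    (zero-burden elements then carry log10(epsilon)).
    """
    counts = count_points_in_elements(elements, somatic.df)
    burden = counts / elements.lengths
    out = elements.with_column("n_mutations", counts).with_column("burden", burden)
    if log_epsilon is not None:
        out = out.with_column("log_burden", np.log10(burden + log_epsilon))
    return out


def burden_group_test(
    elements: ElementSet, group_a: str, group_b: str, column: str = "fate"
) -> dict[str, float]:
    """Two-sided Mann-Whitney U comparison of burden between two groups."""
    df = elements.df
    a = df.loc[df[column] == group_a, "burden"].to_numpy(dtype=float)
    b = df.loc[df[column] == group_b, "burden"].to_numpy(dtype=float)
    if not len(a) or not len(b):
        raise ValidationError("both groups must be non-empty")
    u, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    return {"U": float(u), "p": float(p)}


def gainloss_quintile_proportions(fated: ElementSet) -> pd.DataFrame:
    """Per RT quintile: gains/unchanged and -(losses/unchanged).

    Loss proportions are sign-flipped for the mirror-bar display convention.
    Quintiles with zero unchanged enhancers yield NaN with a warning.
    """
    df = fated.df
    rows = []
    for q, sub in df[df["rt_quintile"] > 0].groupby("rt_quintile", sort=True):
        n_un = int((sub["fate"] == "unchanged").sum())
        n_gain = int((sub["fate"] == "gained").sum())
        n_loss = int((sub["fate"] == "lost").sum())
        if n_un == 0:
            warnings.warn(
                f"quintile {q} has no unchanged enhancers; proportions are NA",
                RuntimeWarning,
                stacklevel=2,
            )
            gp, lp = np.nan, np.nan
        else:
            gp = n_gain / n_un
            lp = -n_loss / n_un
        rows.append((q, n_gain, n_loss, n_un, gp, lp))
    return pd.DataFrame(
        rows,
        columns=[
            "rt_quintile",
            "n_gained",
            "n_lost",
            "n_unchanged",
            "gain_proportion",
            "loss_proportion",
        ],
    )
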