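"""PWM composition, motif scanning, RT enrichment, GC/substitution spectra,
tissue-specificity (tau) and the 2-component Gaussian mixture on binding-site
replication time.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs
from Bio.Seq import Seq
from scipy import stats
from scipy.special import logsumexp
from sklearn.cluster import kmeans_plusplus

from .core import ElementSet, MixtureFit, PositionWeightMatrix, ValidationError

BASES = "ACGT"


# ---------------------------------------------------------------------------
# PWM composition


def consensus_composition(pwm: PositionWeightMatrix) -> dict:
    """Consensus string and nucleotide proportions of a motif.

    A base is called at a position only when its frequency is strictly above
    0.5, otherwise 'N'. GC/AT proportions are counted over the consensus
    relative to the motif length (N positions count toward neither).
    """
    consensus = []
    for row in pwm.freqs:
        best = int(np.argmax(row))
        consensus.append(BASES[best] if row[best] > 0.5 else "N")
    consensus = "".join(consensus)
    length = pwm.length
    gc = sum(1 for b in consensus if b in "CG") / length
    at = sum(1 for b in consensus if b in "AT") / length
    return {"consensus": consensus, "gc_proportion": gc, "at_proportion": at}


# ---------------------------------------------------------------------------
# scanning


def _background_from_sequences(sequences: dict[str, str]) -> dict[str, float]:
    counts = {b: 1.0 for b in BASES}  # +1 smoothing keeps log-odds finite
    for seq in sequences.values():
        up = seq.upper()
        for b in BASES:
            counts[b] += up.count(b)
    total = sum(counts.values())
    return {b: counts[b] / total for b in BASES}


def scan_motifs(
    sequences: dict[str, str],
    pwms: list[PositionWeightMatrix],
    score_frac: float = 0.8,
    background: dict[str, float] | None = None,
    pseudocount: float = 0.01,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Log-odds scan of every motif against both strands of every sequence.

    A sequence carries a motif when its best log-odds score reaches
    ``score_frac`` of the maximum attainable score. Returns the binary
    presence matrix (elements x motifs) and a per-hit table with the best
    score, position and strand.
    """
    if background is None:
        background = _background_from_sequences(sequences)
    presence = pd.DataFrame(
        False, index=list(sequences), columns=[p.id for p in pwms], dtype=bool
    )
    hit_rows = []
    for pwm in pwms:
        counts = {b: (pwm.freqs[:, i] * 1000).tolist() for i, b in enumerate(BASES)}
        motif = bio_motifs.Motif(alphabet=BASES, counts=counts)
        pssm = motif.counts.normalize(pseudocounts=pseudocount).log_odds(background)
        rpssm = pssm.reverse_complement()
        thresholds = (score_frac * pssm.max, score_frac * rpssm.max)
        for name, seq in sequences.items():
            if len(seq) < pwm.length:
                continue
            best = None
            for strand, mat, thr in (("+", pssm, thresholds[0]), ("-", rpssm, thresholds[1])):
                scores = np.asarray(mat.calculate(Seq(seq.upper())), dtype=float)
                if scores.ndim == 0:
                    scores = scores.reshape(1)
                if not len(scores):
                    continue
                i = int(np.nanargmax(scores))
                if scores[i] >= thr and (best is None or scores[i] > best[0]):
                    best = (float(scores[i]), i, strand)
            if best is not None:
                presence.loc[name, pwm.id] = True
                hit_rows.append((name, pwm.id, *best))
    hits = pd.DataFrame(hit_rows, columns=["element", "motif", "score", "position", "strand"])
    return presence, hits


# ---------------------------------------------------------------------------
# RT enrichment


def motif_rt_enrichment(
    present_early: int,
    absent_early: int,
    present_late: int,
    absent_late: int,
    pseudocount: float = 0.0,
) -> float:
    """log2((present_early/absent_early) / (present_late/absent_late)).

    Positive values mean the motif is relatively more frequent at early
    replicating enhancers. Zero cells yield NaN unless a (Haldane-style)
    pseudocount is supplied.
    """
    cells = np.array([present_early, absent_early, present_late, absent_late], dtype=float)
    if pseudocount == 0.0 and (cells == 0).any():
        warnings.warn("zero cell in motif enrichment; returning NA", RuntimeWarning, stacklevel=2)
        return np.nan
    cells = cells + pseudocount
    return float(np.log2((cells[0] / cells[1]) / (cells[2] / cells[3])))


def motif_rt_enrichment_table(
    presence: pd.DataFrame,
    early_ids: list[str],
    late_ids: list[str],
    pseudocount: float = 0.0,
) -> pd.Series:
    """Per-motif early/late enrichment from a presence matrix."""
    if not len(early_ids) or not len(late_ids):
        raise ValidationError("both the early and the late sets must be non-empty")
    early = presence.loc[early_ids]
    late = presence.loc[late_ids]
    out = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for motif in presence.columns:
            out[motif] = motif_rt_enrichment(
                int(early[motif].sum()),
                int((~early[motif]).sum()),
                int(late[motif].sum()),
                int((~late[motif]).sum()),
                pseudocount=pseudocount,
            )
    return pd.Series(out, name="rt_enrichment")


def top_quintile_motifs(scores: pd.Series) -> list[str]:
    """Motif ids in the top quintile by score (high-scoring motif rule)."""
    ranked = scores.sort_values(kind="mergesort")
    chunks = np.array_split(ranked.index.to_numpy(), 5)
    return list(chunks[-1])


# ---------------------------------------------------------------------------
# GC and substitution spectra


def gc_content(seq: str) -> float:
    up = seq.upper()
    acgt = sum(up.count(b) for b in BASES)
    if acgt == 0:
        return np.nan
    return (up.count("G") + up.count("C")) / acgt


def gc_by_quintile(
    sequences: dict[str, str], elements: ElementSet
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-quintile GC% distributions plus pairwise two-sided Mann-Whitney tests.

    Elements need ``id`` and ``rt_quintile`` columns; sequences are keyed by id.
    """
    df = elements.df
    gc = df["id"].map(lambda i: 100.0 * gc_content(sequences[i]))
    per_q = {}
    summary_rows = []
    for q in range(1, 6):
        vals = gc[df["rt_quintile"] == q].to_numpy(dtype=float)
        per_q[q] = vals
        summary_rows.append(
            (q, len(vals), float(np.median(vals)) if len(vals) else np.nan,
             float(np.mean(vals)) if len(vals) else np.nan)
        )
    summary = pd.DataFrame(summary_rows, columns=["rt_quintile", "n", "median_gc", "mean_gc"])
    pair_rows = []
    for qa, qb in itertools.combinations(range(1, 6), 2):
        if len(per_q[qa]) and len(per_q[qb]):
            u, p = stats.mannwhitneyu(per_q[qa], per_q[qb], alternative="two-sided")
        else:
            u, p = np.nan, np.nan
        pair_rows.append((qa, qb, u, p))
    pairs = pd.DataFrame(pair_rows, columns=["quintile_a", "quintile_b", "U", "p"])
    return summary, pairs


def substitution_spectrum(
    ancestor: str, descendant: str, mask_cpg: bool = True, zero_log: float = np.nan
) -> pd.DataFrame:
    """Directional substitution rates between aligned sequences.

    For each ordered pair X->Y (X != Y) the count of substitutions at
    unmasked, ungapped positions is divided by the ancestral count of X and
    log10-transformed. When ``mask_cpg`` is set, both positions of any
    ancestral CpG dinucleotide are excluded (CpG deamination dominates the
    raw spectrum otherwise). Zero rates report ``zero_log`` (NaN by default;
    pass ``-np.inf`` for a sentinel).
    """
    if len(ancestor) != len(descendant):
        raise ValidationError("aligned sequences must have equal length")
    anc = ancestor.upper()
    des = descendant.upper()
    n = len(anc)
    masked = np.zeros(n, dtype=bool)
    if mask_cpg:
        for i in range(n - 1):
            if anc[i] == "C" and anc[i + 1] == "G":
                masked[i] = masked[i + 1] = True
    counts = np.zeros((4, 4), dtype=int)
    anc_counts = np.zeros(4, dtype=int)
    for i in range(n):
        if masked[i] or anc[i] not in BASES or des[i] not in BASES:
            continue
        xi = BASES.index(anc[i])
        anc_counts[xi] += 1
        counts[xi, BASES.index(des[i])] += 1
    rows = []
    for xi, x in enumerate(BASES):
        for yi, y in enumerate(BASES):
            if x == y:
                continue
            c = counts[xi, yi]
            rate = c / anc_counts[xi] if anc_counts[xi] else np.nan
            if rate and np.isfinite(rate):
                log_rate = float(np.log10(rate))
            else:
                log_rate = zero_log if rate == 0 else np.nan
            rows.append((x, y, int(c), int(anc_counts[xi]), rate, log_rate))
    return pd.DataFrame(
        rows, columns=["ref", "alt", "count", "ancestral_count", "rate", "log10_rate"]
    )


# ---------------------------------------------------------------------------
# tissue specificity


def tau(expression_row, n_tissues: int | None = None) -> float:
    """Tissue-specificity index tau in [0, 1].

    tau = sum_i(1 - x_i) / (N - 1) with x_i the expression in tissue i
    divided by the maximum across tissues; 0 = uniform, 1 = single-tissue.
    """
    x = np.asarray(expression_row, dtype=float)
    if n_tissues is not None and len(x) != n_tissues:
        raise ValidationError(f"expected {n_tissues} tissues, got {len(x)}")
    if len(x) < 2:
        raise ValidationError("tau requires at least 2 tissues")
    if (x < 0).any():
        raise ValidationError("expression must be non-negative")
    mx = x.max()
    if mx <= 0:
        raise ValidationError("tau undefined: all-zero expression row")
    return float(np.sum(1.0 - x / mx) / (len(x) - 1))


def tau_table(expression: pd.DataFrame) -> pd.Series:
    return expression.apply(lambda row: tau(row.to_numpy()), axis=1).rename("tau")


def tf_quintile_tau_test(
    enrichment: pd.Series, tau_values: pd.Series
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tau across TF quintiles of motif RT enrichment, with consecutive tests.

    TFs are ranked by their early/late motif enrichment and split into five
    quintiles; quintile 1 holds the most late-enriched TFs. Consecutive
    quintiles are compared by a one-sided Mann-Whitney U test with the
    alternative that the later-replicating quintile has greater tau.
    """
    common = enrichment.dropna().index.intersection(tau_values.dropna().index)
    if len(common) < 5:
        raise ValidationError("need at least 5 TFs with enrichment and tau")
    ranked = enrichment.loc[common].sort_values(kind="mergesort")
    quint = {}
    group_rows = []
    for q, chunk in enumerate(np.array_split(ranked.index.to_numpy(), 5), start=1):
        vals = tau_values.loc[chunk].to_numpy(dtype=float)
        quint[q] = vals
        group_rows.append((q, len(vals), float(np.median(vals))))
    groups = pd.DataFrame(group_rows, columns=["quintile", "n", "median_tau"])
    pair_rows = []
    for q in range(1, 5):  # quintile q replicates later than q+1
        u, p = stats.mannwhitneyu(quint[q], quint[q + 1], alternative="greater")
        pair_rows.append((q, q + 1, float(u), float(p)))
    pairs = pd.DataFrame(pair_rows, columns=["later_quintile", "earlier_quintile", "U", "p"])
    return groups, pairs


# ---------------------------------------------------------------------------
# Gaussian mixture


def fit_gmm2(
    values,
    seed: int = 0,
    max_iter: int = 1000,
    tol: float = 1e-8,
    n_restarts: int = 5,
    sigma_floor: float = 1e-6,
) -> MixtureFit:
    """EM fit of a 2-component univariate Gaussian mixture.

    Means are initialized by k-means++, sigmas at the pooled standard
    deviation, mixing proportions uniformly. The best of ``n_restarts`` runs
    by final log-likelihood is returned, components ordered mu-ascending.
    A floor on sigma prevents full collapse onto repeated values.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 4 or len(np.unique(x)) < 2:
        raise ValidationError("need >=4 observations with >=2 distinct values")
    best: MixtureFit | None = None
    for r in range(n_restarts):
        fit = _em_once(x, seed + r, max_iter, tol, sigma_floor)
        if fit is None:
            continue
        if best is None or fit.loglik > best.loglik:
            best = fit
    if best is None:
        raise ValidationError("all EM restarts degenerated")
    return best


def _em_once(x, seed, max_iter, tol, sigma_floor) -> MixtureFit | None:
    centers, _ = kmeans_plusplus(x.reshape(-1, 1), n_clusters=2, random_state=seed)
    mu = centers.ravel().astype(float)
    pooled = max(x.std(ddof=0), sigma_floor)
    sigma = np.array([pooled, pooled])
    lam = np.array([0.5, 0.5])
    trace = []
    prev = -np.inf
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        log_comp = (
            -0.5 * ((x[:, None] - mu[None, :]) / sigma[None, :]) ** 2
            - np.log(sigma[None, :])
            - 0.5 * np.log(2 * np.pi)
            + np.log(lam[None, :])
        )
        log_norm = logsumexp(log_comp, axis=1)
        loglik = float(log_norm.sum())
        if not np.isfinite(loglik):
            return None
        trace.append(loglik)
        resp = np.exp(log_comp - log_norm[:, None])
        nk = resp.sum(axis=0)
        if (nk < 1e-10).any():
            return None
        lam = nk / len(x)
        mu = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - mu[None, :]) ** 2).sum(axis=0) / nk
        sigma = np.sqrt(np.maximum(var, sigma_floor**2))
        if abs(loglik - prev) < tol:
            break
        prev = loglik
    order = np.argsort(mu)
    return MixtureFit(
        mu=tuple(float(m) for m in mu[order]),
        sigma=tuple(float(s) for s in sigma[order]),
        lam=tuple(float(w) for w in lam[order]),
        loglik=trace[-1],
        n_iter=n_iter,
        loglik_trace=np.asarray(trace),
    )


# ---------------------------------------------------------------------------
# matched background & group comparisons


def gc_matched_background(
    targets: dict[str, str],
    pool: dict[str, str],
    tol: float = 0.02,
    seed: int = 0,
) -> tuple[dict[str, str], list[str]]:
    """Sample, without replacement, pool sequences matched to each target.

    Matching requires |delta GC fraction| <= tol, |delta length| / target
    length <= tol and |delta repeat (soft-masked, lowercase) fraction| <= tol.
    Returns the target->pool assignment and the list of unmatched targets.
    """

    def features(seq: str):
        rep = sum(1 for ch in seq if ch.islower()) / len(seq) if seq else 0.0
        return gc_content(seq), len(seq), rep

    pool_ids = list(pool)
    pool_feats = {pid: features(pool[pid]) for pid in pool_ids}
    available = set(pool_ids)
    rng = np.random.default_rng(seed)
    matched: dict[str, str] = {}
    unmatched: list[str] = []
    for tid, tseq in targets.items():
        tgc, tlen, trep = features(tseq)
        cands = [
            pid
            for pid in available
            if abs(pool_feats[pid][0] - tgc) <= tol
            and abs(pool_feats[pid][1] - tlen) / tlen <= tol
            and abs(pool_feats[pid][2] - trep) <= tol
        ]
        if not cands:
            unmatched.append(tid)
            continue
        # prefer exact feature ties (keeps pool == targets perfectly matchable)
        exact = [pid for pid in cands if pool_feats[pid] == (tgc, tlen, trep)]
        cands = exact or cands
        cands.sort()
        choice = cands[int(rng.integers(0, len(cands)))]
        matched[tid] = choice
        available.remove(choice)
    if unmatched:
        warnings.warn(
            f"{len(unmatched)} target(s) had no GC/length/repeat-matched pool sequence",
            RuntimeWarning,
            stacklevel=2,
        )
    return matched, unmatched


def compare_rt_groups(group_a, group_b, alternative: str = "greater") -> dict[str, float]:
    """Mann-Whitney U rank test between two replication-time samples."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if not len(a) or not len(b):
        raise ValidationError("both groups must be non-empty")
    u, p = stats.mannwhitneyu(a, b, alternative=alternative)
    return {"U": float(u), "p": float(p)}


def top_ranked_summits(
    elements: ElementSet, score_col: str, n: int = 200, extend: int = 250
) -> ElementSet:
    """Top-n elements by activity score, as summit +/- ``extend`` bp intervals.

    The summit is the ``summit`` attribute when present, otherwise the
    interval midpoint.
    """
    df = elements.df.copy()
    if "summit" in df.columns:
        summit = df["summit"].astype(int)
    else:
        summit = (df["start"] + df["end"]) // 2
    df = df.assign(_summit=summit)
    df = df.sort_values(score_col, ascending=False, kind="mergesort").head(n)
    out = df.copy()
    out["start"] = np.maximum(df["_summit"] - extend, 0)
    out["end"] = df["_summit"] + extend
    return ElementSet(out.drop(columns=["_summit"]))
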