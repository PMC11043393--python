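"""Exact 2x2 association statistics shared by the enrichment and DAF modules.

The two-sided p value is the exact (hypergeometric) Fisher test; the point
estimate is the sample cross-product odds ratio ad/bc; the confidence
interval is the exact conditional interval obtained by inverting Fisher's
noncentral hypergeometric test (the convention R's fisher.test uses).
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from scipy.optimize import brentq


def sample_odds_ratio(table: np.ndarray) -> float:
    a, b = table[0]
    c, d = table[1]
    if b * c == 0:
        return np.inf if a * d > 0 else np.nan
    return (a * d) / (b * c)


def fisher_exact_or(table, alternative: str = "two-sided") -> dict[str, float]:
    """Fisher's exact test on a 2x2 count table.

    Returns the sample odds ratio (ad/bc) and the exact p value; never a
    chi-square approximation.
    """
    table = np.asarray(table, dtype=int)
    alt = {"two-sided": "two-sided", "greater": "greater", "less": "less"}[alternative]
    _, p = stats.fisher_exact(table, alternative=alt)
    return {"odds_ratio": float(sample_odds_ratio(table)), "p": float(p)}


def _nch_cdf_tail(x: int, total: int, r1: int, c1: int, psi: float, upper: bool) -> float:
    dist = stats.nchypergeom_fisher(total, c1, r1, psi)
    if upper:
        return float(dist.sf(x - 1))  # P(X >= x)
    return float(dist.cdf(x))  # P(X <= x)


def exact_or_confint(table, alpha: float = 0.05) -> tuple[float, float]:
    """Exact conditional confidence interval for the odds ratio.

    Bounds solve P_psi(X >= x) = alpha/2 (lower) and P_psi(X <= x) = alpha/2
    (upper) under Fisher's noncentral hypergeometric distribution with the
    table's margins. Tables at the support boundary get 0 or inf bounds.
    """
    table = np.asarray(table, dtype=int)
    a, b = table[0]
    c, d = table[1]
    total, r1, c1 = a + b + c + d, a + b, a + c
    lo_support, hi_support = max(0, c1 - (c + d)), min(r1, c1)
    if total == 0 or r1 == 0 or c1 == 0 or r1 == total or c1 == total:
        return (0.0, np.inf)

    def solve(upper_tail: bool) -> float:
        target = alpha / 2

        def f(log_psi):
            return _nch_cdf_tail(a, total, r1, c1, np.exp(log_psi), upper_tail) - target

        lo, hi = -40.0, 40.0
        if f(lo) * f(hi) > 0:
            return 0.0 if upper_tail else np.inf
        return float(np.exp(brentq(f, lo, hi, xtol=1e-10)))

    lower = 0.0 if a == lo_support else solve(upper_tail=True)
    upper = np.inf if a == hi_support else solve(upper_tail=False)
    return (lower, upper)
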