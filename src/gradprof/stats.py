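"""Small statistical primitives used throughout the pipeline.

The rank-sum test here is exact by enumeration for small groups (all
C(n1+n2, n1) assignments of the pooled mid-ranks), switching to the
normal approximation with tie correction for larger samples.  Exactness
for small groups matters because several screens in this pipeline compare
handfuls of clusters or isoform classes.
"""

from __future__ import annotations

from itertools import combinations
from math import comb, erfc, sqrt

import numpy as np
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

from .exceptions import ValidationError

# exact enumeration up to this many distinct assignments (covers 10 vs 10)
_EXACT_MAX_COMBINATIONS = 200_000
_EPS = 1e-12


def wilcoxon_rank_sum(x, y, alternative: str = "two-sided") -> tuple[float, float]:
    """Wilcoxon rank-sum (Mann-Whitney) test of two independent samples.

    Returns ``(statistic, p)`` where the statistic is the rank sum of ``x``
    in the pooled mid-ranked data.  ``alternative`` is ``two-sided``,
    ``greater`` (x tends larger) or ``less``.  For small samples the p-value
    is exact under the permutation null with ties handled by mid-ranks; the
    two-sided p counts assignments at least as far from the null mean as
    observed.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValidationError("rank-sum test needs non-empty groups")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValidationError(f"unknown alternative {alternative!r}")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    w = float(ranks[:n1].sum())
    mu = n1 * (n1 + n2 + 1) / 2.0

    if comb(n1 + n2, n1) <= _EXACT_MAX_COMBINATIONS:
        p = _exact_p(ranks, n1, w, mu, alternative)
    else:
        p = _normal_p(ranks, n1, n2, w, mu, alternative)
    return w, min(1.0, p)


def _exact_p(ranks: np.ndarray, n1: int, w: float, mu: float, alternative: str) -> float:
    n = ranks.size
    total = comb(n, n1)
    ge = le = far = 0
    dev = abs(w - mu)
    for idx in combinations(range(n), n1):
        s = ranks[list(idx)].sum()
        if s >= w - _EPS:
            ge += 1
        if s <= w + _EPS:
            le += 1
        if abs(s - mu) >= dev - _EPS:
            far += 1
    if alternative == "greater":
        return ge / total
    if alternative == "less":
        return le / total
    return far / total


def _normal_p(ranks, n1, n2, w, mu, alternative) -> float:
    n = n1 + n2
    # tie correction on the rank variance
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = float(((counts**3 - counts)).sum())
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return 1.0
    z = (w - mu) / sqrt(var)
    sf = 0.5 * erfc(z / sqrt(2.0))
    cdf = 1.0 - sf
    if alternative == "greater":
        return sf
    if alternative == "less":
        return cdf
    return min(1.0, 2.0 * min(sf, cdf))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg FDR q-values (monotone in raw-p rank order)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def bonferroni_adjust(pvalues) -> np.ndarray:
    """Bonferroni family-wise correction: min(1, m * p)."""
    p = np.asarray(pvalues, dtype=float)
    return np.minimum(1.0, p * p.size)


def ecdf_table(values) -> np.ndarray:
    """Sorted (value, cumulative fraction) pairs for plotting an ECDF."""
    v = np.sort(np.asarray(values, dtype=float))
    frac = np.arange(1, v.size + 1) / v.size
    return np.column_stack([v, frac])
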