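"""Independent brute-force oracles used by the test suite.

These stay deliberately naive — exact combinatorial enumeration with
Fractions, position-by-position scans — so they share no code path with
the implementations they check.
"""

from fractions import Fraction
from itertools import combinations
from math import comb


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n) by exact summation."""
    total = Fraction(0)
    denom = comb(N, n)
    for x in range(k, min(n, K) + 1):
        if n - x > N - K:
            continue
        total += Fraction(comb(K, x) * comb(N - K, n - x), denom)
    return float(total)


def min_hg_prefix_scan(ranked, members) -> tuple[float, int]:
    """Exhaustive prefix scan: (min upper-tail p, optimizing prefix)."""
    members = set(members)
    N = len(ranked)
    K = sum(1 for g in ranked if g in members)
    best_p, best_b = 2.0, 0
    k = 0
    for b, g in enumerate(ranked, start=1):
        if g in members:
            k += 1
        p = hypergeom_upper_tail(k, N, K, b)
        if p < best_p:
            best_p, best_b = p, b
    return best_p, best_b


def exact_rank_sum_p(x, y, alternative="two-sided") -> float:
    """Exact rank-sum p by full enumeration over group assignments,
    mid-ranks for ties."""
    pooled = list(x) + list(y)
    n1 = len(x)
    # mid-ranks computed by hand
    order = sorted(range(len(pooled)), key=lambda i: pooled[i])
    ranks = [0.0] * len(pooled)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and pooled[order[j + 1]] == pooled[order[i]]:
            j += 1
        mid = (i + j) / 2 + 1
        for t in range(i, j + 1):
            ranks[order[t]] = mid
        i = j + 1
    w_obs = sum(ranks[:n1])
    mu = n1 * (len(pooled) + 1) / 2
    eps = 1e-9
    hits = 0
    total = 0
    for idx in combinations(range(len(pooled)), n1):
        s = sum(ranks[i] for i in idx)
        total += 1
        if alternative == "greater":
            hits += s >= w_obs - eps
        elif alternative == "less":
            hits += s <= w_obs + eps
        else:
            hits += abs(s - mu) >= abs(w_obs - mu) - eps
    return hits / total


def count_kmer_occurrences(seq: str, kmer: str) -> int:
    """Overlapping occurrences by position-by-position scan."""
    k = len(kmer)
    return sum(1 for i in range(len(seq) - k + 1) if seq[i:i + k] == kmer)
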