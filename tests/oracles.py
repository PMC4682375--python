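"""Independent brute-force oracles used across the test suite.

Everything here is deliberately naive: exact rational arithmetic and
exhaustive subset enumeration, never the scipy/numpy code paths the
package itself uses.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import combinations
from math import comb


def hypergeom_upper_tail_exact(n_total: int, n_i: int, n_j: int, m: int) -> Fraction:
    """P(|A ∩ B| >= m) for fixed A (|A|=n_i) and uniform random B (|B|=n_j)
    from a universe of n_total, as an exact rational."""
    num = sum(
        comb(n_i, k) * comb(n_total - n_i, n_j - k)
        for k in range(m, min(n_i, n_j) + 1)
        if n_j - k <= n_total - n_i
    )
    return Fraction(num, comb(n_total, n_j))


def overlap_distribution_by_enumeration(n_total: int, n_i: int, n_j: int) -> list[int]:
    """Counts of |A ∩ B| = k over all C(n_total, n_j) subsets B, with
    A = {0..n_i-1} fixed; literal subset enumeration."""
    fixed = set(range(n_i))
    counts = [0] * (min(n_i, n_j) + 1)
    for subset in combinations(range(n_total), n_j):
        counts[len(fixed & set(subset))] += 1
    return counts


def upper_tail_by_enumeration(n_total: int, n_i: int, n_j: int, m: int) -> Fraction:
    counts = overlap_distribution_by_enumeration(n_total, n_i, n_j)
    return Fraction(sum(counts[m:]), comb(n_total, n_j))


def bh_stepup_naive(pvalues: list[float]) -> list[float]:
    """Textbook BH step-up, written index-by-index without vectorization."""
    m = len(pvalues)
    indexed = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank in range(m, 0, -1):
        i = indexed[rank - 1]
        value = min(pvalues[i] * m / rank, 1.0)
        running_min = min(running_min, value)
        adjusted[i] = running_min
    return adjusted
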