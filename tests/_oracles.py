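"""Independent brute-force oracles used to validate the fast implementations.

Everything here is deliberately naive — O(n*m) scans, exact rational
arithmetic, full enumeration — and shares no code with the package paths
it checks.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np


def brute_force_window_counts(chrom_len: int, width: int, reads) -> np.ndarray:
    """Per-window overlap counts by scanning every (read, window) pair."""
    n = -(-chrom_len // width)
    counts = np.zeros(n, dtype=int)
    for s, e in reads:
        for k in range(n):
            ws, we = k * width, min((k + 1) * width, chrom_len)
            if s < we and ws < e:
                counts[k] += 1
    return counts


def brute_force_covered_bases(
    chrom_len: int, width: int, covered_mask: np.ndarray, targets
) -> int:
    """Base-resolution count of target bases inside covered windows."""
    base_covered = np.zeros(chrom_len, dtype=bool)
    for k, cov in enumerate(covered_mask):
        if cov:
            base_covered[k * width : min((k + 1) * width, chrom_len)] = True
    in_target = np.zeros(chrom_len, dtype=bool)
    for s, e in targets:
        in_target[s:e] = True
    return int((base_covered & in_target).sum())


def brute_force_primary_feature(
    start: int, end: int, features, precedence
) -> str:
    """Primary feature by scanning every annotated interval.

    ``features`` is an iterable of (feature_name, start, end) on one
    chromosome; >= 1 bp overlap counts.
    """
    hit = {name for name, fs, fe in features if start < fe and fs < end}
    for name in precedence:
        if name in hit:
            return name
    return "intergenic"


def exact_binomial_two_sided(a: int, b: int) -> Fraction:
    """Conditional binomial(t, 1/2) two-sided p by full rational enumeration."""
    t = a + b
    if t == 0:
        return Fraction(1)
    denom = Fraction(2) ** t
    p_obs = Fraction(comb(t, b), 1) / denom
    total = Fraction(0)
    for x in range(t + 1):
        p_x = Fraction(comb(t, x), 1) / denom
        if p_x <= p_obs:
            total += p_x
    return min(total, Fraction(1))


def exact_hypergeom_upper(k: int, K: int, n: int, N: int) -> Fraction:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), exact rational sum."""
    denom = comb(N, n)
    total = 0
    for x in range(k, min(K, n) + 1):
        total += comb(K, x) * comb(N - K, n - x)
    return Fraction(total, denom)


def exact_fisher_two_sided(a: int, b: int, c: int, d: int) -> Fraction:
    """Two-sided Fisher p by enumerating all tables with the observed margins."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if n == 0:
        return Fraction(1)
    denom = comb(n, c1)
    p_obs = Fraction(comb(r1, a) * comb(r2, c), denom)
    total = Fraction(0)
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        p_x = Fraction(comb(r1, x) * comb(r2, c1 - x), denom)
        if p_x <= p_obs:
            total += p_x
    return min(total, Fraction(1))
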