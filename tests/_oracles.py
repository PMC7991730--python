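"""Independent brute-force oracles used to validate the statistical kernels.

These deliberately avoid the code paths (and scipy routines) they check:
hypergeometric tails come from exact rational combinatorics and literal
subset enumeration, Mann-Whitney P-values from full labeling enumeration,
and Spearman P-values from full permutation enumeration.
"""
from __future__ import annotations

from fractions import Fraction
from itertools import combinations, permutations
from math import comb

import numpy as np


def hypergeom_tail_fraction(k: int, s1: int, s2: int, n: int) -> Fraction:
    """P(X >= k) as an exact rational from the counting identity."""
    total = comb(n, s2)
    num = sum(comb(s1, j) * comb(n - s1, s2 - j) for j in range(k, min(s1, s2) + 1))
    return Fraction(num, total)


def hypergeom_tail_enumerate(k: int, s1: int, s2: int, n: int) -> Fraction:
    """P(X >= k) by literally enumerating all C(n, s2) draws."""
    marked = set(range(s1))
    hits = sum(1 for draw in combinations(range(n), s2) if len(marked & set(draw)) >= k)
    return Fraction(hits, comb(n, s2))


def mwu_two_sided_enumerate(a, b) -> float:
    """Two-sided Mann-Whitney P by enumerating all group labelings.

    For tie-free data: U = pairs where an a-value exceeds a b-value; the
    two-sided P is min(1, 2 * min(P(U <= u), P(U >= u))) under the
    permutation null.
    """
    a = list(a)
    b = list(b)
    pooled = a + b
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    na = len(a)
    u_obs = sum(1 for x in a for y in b if x > y)
    us = []
    for idx in combinations(range(len(pooled)), na):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(len(pooled)) if i not in set(idx)]
        us.append(sum(1 for x in ga for y in gb if x > y))
    us = np.asarray(us)
    p_le = np.mean(us <= u_obs)
    p_ge = np.mean(us >= u_obs)
    return min(1.0, 2.0 * min(p_le, p_ge))


def spearman_rho(x, y) -> float:
    """Spearman rho for tie-free data via the rank-difference formula."""
    x = np.asarray(x)
    y = np.asarray(y)
    rx = np.argsort(np.argsort(x))
    ry = np.argsort(np.argsort(y))
    n = x.size
    d = rx - ry
    return 1.0 - 6.0 * float(d @ d) / (n * (n * n - 1))


def spearman_two_sided_enumerate(x, y) -> float:
    """Two-sided Spearman P by enumerating all n! rank pairings."""
    rho_obs = abs(spearman_rho(x, y))
    n = len(x)
    count = 0
    total = 0
    for perm in permutations(range(n)):
        d = np.arange(n) - np.asarray(perm)
        rho = 1.0 - 6.0 * float(d @ d) / (n * (n * n - 1))
        if abs(rho) >= rho_obs - 1e-12:
            count += 1
        total += 1
    return count / total
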