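"""Rank-rank hypergeometric overlap (RRHO) between two signed rankings.

Elements (DMRs or genes) are ranked by a signed significance score,
sign(diff) * -log10(P): significantly hypermethylated elements sit at the
top of the list, significantly hypomethylated ones at the bottom, and
unchanged elements in the middle.  For every pair of rank thresholds the
overlap of the two top-lists is scored with a hypergeometric upper-tail
P-value, giving a threshold-free map of shared enrichment.  Concordant
element sets are extracted either by sign agreement (default) or from the
most enriched map quadrant, and confirmed by Spearman correlation of the
effect sizes.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import permutations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "signed_score",
    "rank_elements",
    "hypergeom_upper_tail",
    "RrhoResult",
    "rrho_map",
    "bonferroni_cell_line",
    "extract_concordant",
    "effect_spearman",
]

P_FLOOR = 1e-300  # guards -log10 against float underflow of tiny P-values


def signed_score(diff: float, p: float) -> float:
    """Signed significance score sign(diff) * -log10(p), P floored at 1e-300."""
    if np.isnan(diff) or np.isnan(p):
        return float("nan")
    return float(np.sign(diff) * -np.log10(max(p, P_FLOOR)))


def rank_elements(scores: Mapping[str, float]) -> list[str]:
    """Element ids in descending score order; ties broken lexicographically."""
    ids = list(scores)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate element ids")
    return sorted(ids, key=lambda e: (-scores[e], e))


def hypergeom_upper_tail(k: int, s1: int, s2: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(population n, s1 marked, s2 drawn)."""
    if not (0 <= k <= min(s1, s2) <= n) or s1 > n or s2 > n:
        raise ValueError(f"invalid hypergeometric bounds k={k}, s1={s1}, s2={s2}, n={n}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, n, s1, s2))


@dataclass
class RrhoResult:
    """Threshold-pair enrichment map plus the extracted overlap sets."""

    n: int
    step: int
    thresholds: np.ndarray  # rank thresholds shared by both axes
    map: np.ndarray  # -log10 upper-tail P at each (i, j) threshold pair
    best_cell: tuple[int, int]  # indices into thresholds maximizing map
    best_logp: float
    overlap_up: set[str]
    overlap_down: set[str]

    @property
    def concordant(self) -> set[str]:
        return self.overlap_up | self.overlap_down

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.map, index=self.thresholds, columns=self.thresholds)


def _enrichment_map(
    pos_a: np.ndarray, pos_b: np.ndarray, thresholds: np.ndarray, n: int
) -> np.ndarray:
    """-log10 hypergeometric upper-tail P over the threshold grid.

    pos_a/pos_b are each element's 0-based rank in the two lists; cell (i, j)
    scores k = |top_i(a) & top_j(b)| against Hypergeometric(n, t_i, t_j).
    """
    edges = np.concatenate([[0], thresholds])
    counts, _, _ = np.histogram2d(pos_a, pos_b, bins=[edges, edges])
    k = counts.cumsum(axis=0).cumsum(axis=1)
    t1 = thresholds[:, None]
    t2 = thresholds[None, :]
    with np.errstate(divide="ignore"):
        p = stats.hypergeom.sf(k - 1, n, t1, t2)
    return -np.log10(np.maximum(p, P_FLOOR))


def rrho_map(
    ranked_a: Sequence[str], ranked_b: Sequence[str], step: int | None = None
) -> RrhoResult:
    """RRHO enrichment map between two rankings of the same element set.

    Elements absent from either list are dropped (intersection first).  The
    grid strides ranks in steps of ``step`` (default n // 100, at least 1).
    Cells score enrichment (upper tail) only.  The up-overlap set is read at
    the best cell of the map; the down-overlap set at the best cell of the
    map on both rankings reversed.
    """
    common = set(ranked_a) & set(ranked_b)
    a = [e for e in ranked_a if e in common]
    b = [e for e in ranked_b if e in common]
    n = len(a)
    if n < 2:
        raise ValueError("need at least 2 shared elements")
    if step is None:
        step = max(1, n // 100)
    pos_a = {e: i for i, e in enumerate(a)}
    pos_b = {e: i for i, e in enumerate(b)}
    pa = np.array([pos_a[e] for e in common])
    pb = np.array([pos_b[e] for e in common])
    thresholds = np.arange(step, n + 1, step)

    logmap = _enrichment_map(pa, pb, thresholds, n)
    best_flat = int(np.argmax(logmap))
    bi, bj = np.unravel_index(best_flat, logmap.shape)
    ti, tj = int(thresholds[bi]), int(thresholds[bj])
    up = {e for e in common if pos_a[e] < ti and pos_b[e] < tj}

    down_map = _enrichment_map(n - 1 - pa, n - 1 - pb, thresholds, n)
    di, dj = np.unravel_index(int(np.argmax(down_map)), down_map.shape)
    tdi, tdj = int(thresholds[di]), int(thresholds[dj])
    down = {e for e in common if (n - 1 - pos_a[e]) < tdi and (n - 1 - pos_b[e]) < tdj}

    return RrhoResult(
        n=n,
        step=step,
        thresholds=thresholds,
        map=logmap,
        best_cell=(int(bi), int(bj)),
        best_logp=float(logmap[bi, bj]),
        overlap_up=up,
        overlap_down=down,
    )


def bonferroni_cell_line(result: RrhoResult, alpha: float = 0.05) -> float:
    """-log10 significance line after Bonferroni over all map cells."""
    return float(-np.log10(alpha / result.map.size))


def extract_concordant(
    scores_a: Mapping[str, float],
    scores_b: Mapping[str, float],
    mode: str = "sign",
) -> tuple[set[str], set[str]]:
    """Concordant (same-direction) element sets between two comparisons.

    ``sign``: up = score > 0 in both, down = score < 0 in both.
    ``rrho_quadrant``: elements inside the top-tails at the best enrichment
    cell (up) and inside the bottom-tails at the best depletion-side cell
    (down) of the RRHO map.
    """
    shared = set(scores_a) & set(scores_b)
    if mode == "sign":
        up = {e for e in shared if scores_a[e] > 0 and scores_b[e] > 0}
        down = {e for e in shared if scores_a[e] < 0 and scores_b[e] < 0}
        return up, down
    if mode == "rrho_quadrant":
        sub_a = {e: scores_a[e] for e in shared}
        sub_b = {e: scores_b[e] for e in shared}
        result = rrho_map(rank_elements(sub_a), rank_elements(sub_b))
        return result.overlap_up, result.overlap_down
    raise ValueError(f"unknown mode {mode!r}")


def _exact_spearman_p(ra: np.ndarray, rb: np.ndarray, rho_obs: float) -> float:
    """Two-sided permutation P for tie-free ranks by full enumeration."""
    n = ra.size
    order = rb[np.argsort(ra)]
    denom = n * (n * n - 1)
    count = 0
    total = 0
    target = abs(rho_obs) - 1e-12
    base = np.arange(n)
    for perm in permutations(range(n)):
        d = base - np.asarray(perm)
        rho = 1.0 - 6.0 * float(d @ d) / denom
        if abs(rho) >= target:
            count += 1
        total += 1
    return count / total


def effect_spearman(
    effect_a: Sequence[float], effect_b: Sequence[float]
) -> tuple[float, float]:
    """Spearman rank correlation of effect sizes with two-sided P.

    Exact permutation P (full enumeration) for tie-free data with n <= 9;
    t-approximation otherwise.  Constant input yields (NaN, NaN) with a
    warning.
    """
    a = np.asarray(effect_a, dtype=float)
    b = np.asarray(effect_b, dtype=float)
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    if a.size < 3:
        raise ValueError("need at least 3 elements")
    if np.unique(a).size == 1 or np.unique(b).size == 1:
        warnings.warn("effect_spearman: constant vector, rho undefined")
        return float("nan"), float("nan")
    res = stats.spearmanr(a, b)
    rho = float(res.statistic)
    tie_free = np.unique(a).size == a.size and np.unique(b).size == b.size
    if tie_free and a.size <= 9:
        ra = stats.rankdata(a).astype(int) - 1
        rb = stats.rankdata(b).astype(int) - 1
        return rho, _exact_spearman_p(ra, rb, rho)
    return rho, float(res.pvalue)
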