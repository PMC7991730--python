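"""Differentially methylated region calling by CpG chaining, recursive
binary segmentation of the group-difference profile, and Mann-Whitney
testing of per-sample region levels.

A region qualifies as a DMR when it spans >= 5 CpGs with adjacent gaps
<= 300 bp, shows an absolute group-mean methylation difference > 0.1, and
survives Bonferroni correction at P < 0.05 over the segments actually
tested in the comparison.  The per-sample test unit is the depth-weighted
region level, so n per side equals the number of animals.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import Comparison
from .quant import MethylationMatrix

__all__ = [
    "CandidateWindow",
    "Dmr",
    "DmrCallSet",
    "chain_candidates",
    "mwu_test",
    "segment",
    "call_dmrs",
    "dmrs_to_bed",
]


@dataclass(frozen=True)
class CandidateWindow:
    """A maximal run of testable CpGs with bounded inter-site gaps."""

    chrom: str
    start: int
    end: int  # half-open: last CpG position + 1
    site_indices: tuple[int, ...]


@dataclass(frozen=True)
class Dmr:
    dmr_id: str
    chrom: str
    start: int
    end: int
    n_cpgs: int
    mean_a: float
    mean_b: float
    diff: float  # mean_a - mean_b
    p_raw: float
    p_adj: float
    direction: str  # hyper/hypo with respect to group_a
    site_indices: tuple[int, ...] = field(default=(), compare=False, repr=False)


@dataclass
class DmrCallSet:
    """DMRs called for one comparison plus testing metadata."""

    comparison: Comparison
    dmrs: list[Dmr]
    n_tested: int

    def __iter__(self) -> Iterator[Dmr]:
        return iter(self.dmrs)

    def __len__(self) -> int:
        return len(self.dmrs)

    def __getitem__(self, i):
        return self.dmrs[i]


def chain_candidates(
    matrix: MethylationMatrix, max_gap: int = 300, min_cpgs: int = 5
) -> list[CandidateWindow]:
    """Chain consecutive testable CpGs into candidate windows.

    Runs break at chromosome boundaries and wherever adjacent cytosines are
    more than max_gap apart; runs shorter than min_cpgs are discarded.
    """
    chroms = matrix.sites["chrom"].to_numpy()
    pos = matrix.sites["pos"].to_numpy()
    windows: list[CandidateWindow] = []
    n = len(pos)
    i = 0
    while i < n:
        j = i
        while (
            j + 1 < n
            and chroms[j + 1] == chroms[j]
            and pos[j + 1] - pos[j] <= max_gap
        ):
            j += 1
        if j - i + 1 >= min_cpgs:
            windows.append(
                CandidateWindow(
                    chrom=str(chroms[i]),
                    start=int(pos[i]),
                    end=int(pos[j]) + 1,
                    site_indices=tuple(range(i, j + 1)),
                )
            )
        i = j + 1
    return windows


def mwu_test(values_a: Sequence[float], values_b: Sequence[float]) -> float:
    """Two-sided Mann-Whitney U P-value on per-sample levels.

    Uses the exact null distribution for tie-free data when the smaller
    group has <= 8 observations, otherwise the normal approximation with
    tie correction.  Returns NaN (with a warning) when a side has fewer
    than 2 non-missing values.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if min(a.size, b.size) < 2:
        warnings.warn("mwu_test: fewer than 2 values on a side; P is missing")
        return float("nan")
    combined = np.concatenate([a, b])
    has_ties = np.unique(combined).size < combined.size
    method = "exact" if (not has_ties and min(a.size, b.size) <= 8) else "asymptotic"
    return float(stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)


def _diff_profile(
    matrix: MethylationMatrix, comparison: Comparison
) -> np.ndarray:
    """Per-CpG difference of group-mean ratios, mean(group_a) - mean(group_b)."""
    ratio = matrix.ratio
    ia = matrix.sample_indices(comparison.group_a)
    ib = matrix.sample_indices(comparison.group_b)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows stay NaN
        return np.nanmean(ratio[:, ia], axis=1) - np.nanmean(ratio[:, ib], axis=1)


def segment(
    window: CandidateWindow,
    matrix: MethylationMatrix,
    comparison: Comparison,
    min_cpgs: int = 5,
    improve_eps: float = 0.02,
) -> list[CandidateWindow]:
    """Recursive binary segmentation of the per-CpG difference profile.

    At each step every split leaving >= min_cpgs CpGs on both sides is
    scored by max(|diff_left|, |diff_right|); the window is split at the
    best point only if that score beats |diff_parent| + improve_eps, and
    both halves are refined recursively.  Otherwise the window is emitted
    unchanged.  Emitted sub-windows never overlap.
    """
    profile = _diff_profile(matrix, comparison)
    pos = matrix.sites["pos"].to_numpy()

    def mean_diff(idx: np.ndarray) -> float:
        vals = profile[idx]
        vals = vals[~np.isnan(vals)]
        return float(vals.mean()) if vals.size else 0.0

    def recurse(idx: np.ndarray) -> list[CandidateWindow]:
        m = idx.size
        parent = abs(mean_diff(idx))
        best_score, best_split = -np.inf, None
        for s in range(min_cpgs, m - min_cpgs + 1):
            score = max(abs(mean_diff(idx[:s])), abs(mean_diff(idx[s:])))
            if score > best_score:
                best_score, best_split = score, s
        if best_split is not None and best_score > parent + improve_eps:
            return recurse(idx[:best_split]) + recurse(idx[best_split:])
        return [
            CandidateWindow(
                chrom=window.chrom,
                start=int(pos[idx[0]]),
                end=int(pos[idx[-1]]) + 1,
                site_indices=tuple(int(i) for i in idx),
            )
        ]

    return recurse(np.asarray(window.site_indices, dtype=int))


def call_dmrs(
    matrix: MethylationMatrix,
    comparison: Comparison,
    max_gap: int = 300,
    min_cpgs: int = 5,
    min_abs_diff: float = 0.1,
    alpha: float = 0.05,
    improve_eps: float = 0.02,
) -> DmrCallSet:
    """Call DMRs for one comparison on a missingness-filtered matrix.

    Pipeline: chain candidate windows, segment each, test every segment's
    per-sample region levels with the Mann-Whitney U test, Bonferroni-adjust
    over the number of tested segments, then keep segments meeting all
    printed criteria (n_cpgs >= min_cpgs, |diff| > min_abs_diff strictly,
    adjusted P < alpha).
    """
    ia = matrix.sample_indices(comparison.group_a)
    ib = matrix.sample_indices(comparison.group_b)
    tested: list[tuple[CandidateWindow, float, float, float, float]] = []
    for window in chain_candidates(matrix, max_gap=max_gap, min_cpgs=min_cpgs):
        for seg in segment(
            window, matrix, comparison, min_cpgs=min_cpgs, improve_eps=improve_eps
        ):
            levels = matrix.region_levels(np.asarray(seg.site_indices, dtype=int))
            va, vb = levels[ia], levels[ib]
            if min(np.sum(~np.isnan(va)), np.sum(~np.isnan(vb))) < 2:
                continue
            p = mwu_test(va, vb)
            if np.isnan(p):
                continue
            mean_a = float(np.nanmean(va))
            mean_b = float(np.nanmean(vb))
            tested.append((seg, mean_a, mean_b, mean_a - mean_b, p))

    n_tested = len(tested)
    dmrs: list[Dmr] = []
    for k, (seg, mean_a, mean_b, diff, p) in enumerate(tested):
        p_adj = min(1.0, p * n_tested)
        if len(seg.site_indices) >= min_cpgs and abs(diff) > min_abs_diff and p_adj < alpha:
            dmrs.append(
                Dmr(
                    dmr_id=f"dmr_{len(dmrs) + 1}",
                    chrom=seg.chrom,
                    start=seg.start,
                    end=seg.end,
                    n_cpgs=len(seg.site_indices),
                    mean_a=mean_a,
                    mean_b=mean_b,
                    diff=diff,
                    p_raw=p,
                    p_adj=p_adj,
                    direction="hyper" if diff > 0 else "hypo",
                    site_indices=seg.site_indices,
                )
            )
    return DmrCallSet(comparison=comparison, dmrs=dmrs, n_tested=n_tested)


def dmrs_to_bed(callset: DmrCallSet) -> pd.DataFrame:
    """BED6+ table: chrom, start, end, name, score (-log10 p_adj capped at
    300), strand '.', then the full DMR statistics."""
    rows = []
    for d in callset:
        score = min(300.0, -np.log10(max(d.p_adj, 1e-300)))
        rows.append(
            (
                d.chrom, d.start, d.end, d.dmr_id, score, ".",
                d.n_cpgs, d.mean_a, d.mean_b, d.diff, d.p_raw, d.p_adj, d.direction,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "start", "end", "name", "score", "strand",
            "n_cpgs", "mean_a", "mean_b", "diff", "p_raw", "p_adj", "direction",
        ],
    )
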