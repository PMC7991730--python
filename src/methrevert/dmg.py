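"""Promoter mapping of DMRs and differentially methylated gene calls.

A gene becomes a DMG when at least one DMR overlaps its promoter by more
than 50% of the DMR's length and the whole promoter shows a significant
methylation difference (Mann-Whitney U, P < 0.05) between the two groups.
Fold changes use the signed-ratio convention: r = mean_a/mean_b reported
as r when r >= 1 and as -1/r otherwise, so |FC| >= 1 always.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import Comparison, Promoter
from .dmr import Dmr, DmrCallSet, mwu_test
from .quant import MethylationMatrix

__all__ = ["Dmg", "overlap_fraction", "fold_change", "call_dmgs", "dmgs_to_table"]


@dataclass(frozen=True)
class Dmg:
    gene_id: str
    supporting_dmrs: tuple[str, ...]
    promoter_mean_a: float
    promoter_mean_b: float
    p_promoter: float
    fc_signed: float
    direction: str  # hyper/hypo w.r.t. group_a


def overlap_fraction(dmr, promoter) -> float:
    """Fraction of the DMR's length covered by the promoter interval.

    Accepts any objects carrying chrom/start/end (half-open).  Different
    chromosomes yield 0; a zero-length DMR is an error.
    """
    if dmr.end <= dmr.start:
        raise ValueError("zero-length DMR interval")
    if dmr.chrom != promoter.chrom:
        return 0.0
    overlap = min(dmr.end, promoter.end) - max(dmr.start, promoter.start)
    return max(0, overlap) / (dmr.end - dmr.start)


def fold_change(mean_a: float, mean_b: float) -> float:
    """Signed ratio of group means: +r if mean_a/mean_b >= 1, else -1/r."""
    if not (mean_a > 0 and mean_b > 0):
        warnings.warn("fold_change undefined for non-positive means")
        return float("nan")
    r = mean_a / mean_b
    return r if r >= 1 else -1.0 / r


def call_dmgs(
    dmrs: DmrCallSet | Sequence[Dmr],
    promoters: Sequence[Promoter],
    matrix: MethylationMatrix,
    comparison: Comparison,
    alpha: float = 0.05,
    min_overlap: float = 0.5,
) -> list[Dmg]:
    """Call DMGs from a DMR list and promoter annotation.

    Each DMR supports every promoter it overlaps by more than min_overlap of
    its own length (a DMR may support several overlapping promoters).  For
    each supported gene the promoter-wide per-sample region levels are tested
    with the Mann-Whitney U test; genes with P < alpha are returned,
    one non-redundant record per gene, sorted by gene id.
    """
    gene_dmrs: dict[str, list[str]] = {}
    gene_promoter: dict[str, Promoter] = {}
    for promoter in promoters:
        for d in dmrs:
            if overlap_fraction(d, promoter) > min_overlap:
                gene_dmrs.setdefault(promoter.gene_id, []).append(d.dmr_id)
                gene_promoter[promoter.gene_id] = promoter

    ia = matrix.sample_indices(comparison.group_a)
    ib = matrix.sample_indices(comparison.group_b)
    out: list[Dmg] = []
    for gene_id in sorted(gene_dmrs):
        promoter = gene_promoter[gene_id]
        sites = matrix.sites_in(promoter.chrom, promoter.start, promoter.end)
        if sites.size == 0:
            continue
        levels = matrix.region_levels(sites)
        p = mwu_test(levels[ia], levels[ib])
        if np.isnan(p) or p >= alpha:
            continue
        mean_a = float(np.nanmean(levels[ia]))
        mean_b = float(np.nanmean(levels[ib]))
        out.append(
            Dmg(
                gene_id=gene_id,
                supporting_dmrs=tuple(gene_dmrs[gene_id]),
                promoter_mean_a=mean_a,
                promoter_mean_b=mean_b,
                p_promoter=p,
                fc_signed=fold_change(mean_a, mean_b),
                direction="hyper" if mean_a > mean_b else "hypo",
            )
        )
    return out


def dmgs_to_table(dmgs: Sequence[Dmg]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in dmgs],
            "n_dmrs": [len(g.supporting_dmrs) for g in dmgs],
            "dmr_ids": [",".join(g.supporting_dmrs) for g in dmgs],
            "mean_a": [g.promoter_mean_a for g in dmgs],
            "mean_b": [g.promoter_mean_b for g in dmgs],
            "p_promoter": [g.p_promoter for g in dmgs],
            "fc_signed": [g.fc_signed for g in dmgs],
            "direction": [g.direction for g in dmgs],
        }
    )
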