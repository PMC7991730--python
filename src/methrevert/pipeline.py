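"""Orchestration of the three-comparison diet-reversal methylome analysis.

The design has three diet groups: lean controls on standard chow (SD), a
high fat/fructose/cholesterol group (FFC), and a diet-normalization group
returned to chow after the FFC diet (FFC/SD).  Three pairwise comparisons
are analysed: FFC vs SD, FFC vs FFC/SD, and FFC/SD vs SD.

Two panels are assembled:

* the core panel — DMRs of FFC vs SD and FFC vs FFC/SD that change in the
  same direction in the other comparison (RRHO concordance), mapped to
  promoters, kept when the promoter differs from SD or from FFC/SD
  (Mann-Whitney P < 0.05), then partitioned into reversible genes (promoter
  comparable between FFC/SD and SD, P > 0.05) and retained genes;
* the persistence panel — concordant DMRs of FFC vs SD and FFC/SD vs SD
  whose genes differ from SD in FFC or FFC/SD while FFC and FFC/SD are
  equivalent (promoter P >= 0.05), i.e. changes that survive diet reversal.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .core_io import Comparison, Promoter, write_table
from .dmg import Dmg, call_dmgs, dmgs_to_table, fold_change, overlap_fraction
from .dmr import Dmr, DmrCallSet, call_dmrs, dmrs_to_bed, mwu_test
from .quant import MethylationMatrix, filter_missing_by_group
from .rrho import extract_concordant, signed_score

__all__ = [
    "StudyDesign",
    "PipelineParams",
    "PanelResult",
    "score_regions",
    "run_core_panel",
    "run_persistence_panel",
    "classify_reversibility",
    "run_pipeline",
]

logger = logging.getLogger("methrevert")


@dataclass
class StudyDesign:
    """Group assignment and the three principal comparisons."""

    groups: dict[str, list[str]]
    control: str = "SD"
    treatment: str = "FFC"
    reversal: str = "FFC/SD"

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for label, samples in self.groups.items():
            overlap = seen & set(samples)
            if overlap:
                raise ValueError(f"samples in more than one group: {sorted(overlap)}")
            seen |= set(samples)
        for label in (self.control, self.treatment, self.reversal):
            if label not in self.groups or not self.groups[label]:
                raise ValueError(f"design group {label!r} is missing or empty")

    @classmethod
    def from_groups(cls, groups: Mapping[str, str], **kw) -> "StudyDesign":
        """Build from a sample_id -> label mapping."""
        by_label: dict[str, list[str]] = {}
        for sample, label in groups.items():
            by_label.setdefault(label, []).append(sample)
        return cls(groups=by_label, **kw)

    @property
    def comparisons(self) -> list[Comparison]:
        return [
            Comparison.versus(self.treatment, self.control),
            Comparison.versus(self.treatment, self.reversal),
            Comparison.versus(self.reversal, self.control),
        ]

    def sample_groups(self) -> dict[str, str]:
        return {s: label for label, ss in self.groups.items() for s in ss}


@dataclass
class PipelineParams:
    """All analysis thresholds in one place (defaults follow the study)."""

    min_depth: int = 4
    max_missing_frac: float = 0.3
    missing_scope: str = "comparison"  # or "all_groups"
    max_gap: int = 300
    min_cpgs: int = 5
    min_abs_diff: float = 0.1
    alpha: float = 0.05
    improve_eps: float = 0.02
    min_overlap: float = 0.5
    concordance_mode: str = "sign"  # or "rrho_quadrant"
    equivalence_alpha: float = 0.05
    correlation_rule: str = "and"  # tier thresholds combined conjunctively

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineParams":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data.get("params", data))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"params": asdict(self)}, fh, sort_keys=False)


@dataclass
class PanelResult:
    """Core panel output: concordant DMRs, the merged gene panel, and its
    reversible/retained partition."""

    dmr_sets: dict[str, DmrCallSet]
    core_dmrs: list[Dmr]
    core_genes: pd.DataFrame  # one row per gene with per-comparison statistics
    reversible_genes: set[str]
    retained_genes: set[str]
    persistent_genes: pd.DataFrame | None = None

    @property
    def core_gene_ids(self) -> set[str]:
        return set(self.core_genes["gene_id"]) if len(self.core_genes) else set()


def score_regions(
    matrix: MethylationMatrix,
    comparison: Comparison,
    regions: Sequence,
) -> dict[str, float]:
    """Signed significance scores of arbitrary regions in one comparison.

    For each region (anything with dmr_id/chrom/start/end) the per-sample
    depth-weighted levels are compared between the groups; the score is
    sign(diff) * -log10(P).  Regions with no testable site get NaN.
    """
    ia = matrix.sample_indices(comparison.group_a)
    ib = matrix.sample_indices(comparison.group_b)
    scores: dict[str, float] = {}
    for region in regions:
        sites = matrix.sites_in(region.chrom, region.start, region.end)
        if sites.size == 0:
            scores[region.dmr_id] = float("nan")
            continue
        levels = matrix.region_levels(sites)
        va, vb = levels[ia], levels[ib]
        if min(np.sum(~np.isnan(va)), np.sum(~np.isnan(vb))) < 2:
            scores[region.dmr_id] = float("nan")
            continue
        p = mwu_test(va, vb)
        diff = float(np.nanmean(va) - np.nanmean(vb))
        scores[region.dmr_id] = signed_score(diff, p)
    return scores


def _prepare(
    matrix: MethylationMatrix, comparison: Comparison, params: PipelineParams
) -> MethylationMatrix:
    return filter_missing_by_group(
        matrix,
        comparison,
        max_missing_frac=params.max_missing_frac,
        scope=params.missing_scope,
    )


def _call(
    matrix: MethylationMatrix, comparison: Comparison, params: PipelineParams
) -> tuple[MethylationMatrix, DmrCallSet]:
    filtered = _prepare(matrix, comparison, params)
    callset = call_dmrs(
        filtered,
        comparison,
        max_gap=params.max_gap,
        min_cpgs=params.min_cpgs,
        min_abs_diff=params.min_abs_diff,
        alpha=params.alpha,
        improve_eps=params.improve_eps,
    )
    logger.info(
        "dmr %s: %d sites tested in %d segments, %d DMRs",
        comparison.name, filtered.n_sites, callset.n_tested, len(callset),
    )
    return filtered, callset


def _concordant_union(
    set_a: DmrCallSet,
    matrix_b: MethylationMatrix,
    set_b: DmrCallSet,
    matrix_a: MethylationMatrix,
    mode: str,
) -> list[Dmr]:
    """DMRs of each list whose direction agrees with the other comparison."""
    tagged_a = [_retag(d, set_a.comparison) for d in set_a]
    tagged_b = [_retag(d, set_b.comparison) for d in set_b]
    union: list[Dmr] = []
    for tagged, own_set, other_matrix, other_cmp in (
        (tagged_a, set_a, matrix_b, set_b.comparison),
        (tagged_b, set_b, matrix_a, set_a.comparison),
    ):
        if not tagged:
            continue
        own_scores = {d.dmr_id: signed_score(d.diff, d.p_raw) for d in tagged}
        other_scores = score_regions(other_matrix, other_cmp, tagged)
        up, down = extract_concordant(own_scores, other_scores, mode=mode)
        keep = up | down
        union.extend(d for d in tagged if d.dmr_id in keep)
        logger.info(
            "rrho %s against %s: %d of %d DMRs concordant",
            own_set.comparison.name, other_cmp.name, len(keep), len(tagged),
        )
    return union


def _retag(d: Dmr, comparison: Comparison) -> Dmr:
    """Prefix the DMR id with its comparison so ids are unique in unions."""
    prefix = comparison.name.replace(" ", "").replace("/", "")
    if d.dmr_id.startswith(prefix):
        return d
    return Dmr(
        dmr_id=f"{prefix}:{d.dmr_id}",
        chrom=d.chrom, start=d.start, end=d.end, n_cpgs=d.n_cpgs,
        mean_a=d.mean_a, mean_b=d.mean_b, diff=d.diff,
        p_raw=d.p_raw, p_adj=d.p_adj, direction=d.direction,
        site_indices=d.site_indices,
    )


def _map_to_genes(
    core_dmrs: Sequence[Dmr], promoters: Sequence[Promoter], min_overlap: float
) -> dict[str, list[str]]:
    genes: dict[str, list[str]] = {}
    for promoter in promoters:
        for d in core_dmrs:
            if overlap_fraction(d, promoter) > min_overlap:
                genes.setdefault(promoter.gene_id, []).append(d.dmr_id)
    return genes


def _promoter_stats(
    matrix: MethylationMatrix, comparison: Comparison, promoter: Promoter
) -> tuple[float, float, float, float]:
    """(p, mean_a, mean_b, fc_signed) of the whole promoter in one comparison."""
    sites = matrix.sites_in(promoter.chrom, promoter.start, promoter.end)
    if sites.size == 0:
        return (float("nan"),) * 4
    levels = matrix.region_levels(sites)
    ia = matrix.sample_indices(comparison.group_a)
    ib = matrix.sample_indices(comparison.group_b)
    va, vb = levels[ia], levels[ib]
    if min(np.sum(~np.isnan(va)), np.sum(~np.isnan(vb))) < 2:
        return (float("nan"),) * 4
    p = mwu_test(va, vb)
    mean_a = float(np.nanmean(va))
    mean_b = float(np.nanmean(vb))
    return p, mean_a, mean_b, fold_change(mean_a, mean_b)


def run_core_panel(
    matrix: MethylationMatrix,
    promoters: Sequence[Promoter],
    design: StudyDesign,
    params: PipelineParams | None = None,
) -> PanelResult:
    """Assemble the core DMG panel of FFC-diet-driven methylation changes.

    Steps: call DMRs for treatment-vs-control and treatment-vs-reversal;
    keep DMRs concordant with the other comparison; map the union to
    promoters; keep genes whose promoter differs in either comparison
    (P < alpha); merge the two significant gene sets; finally partition the
    panel by reversibility against the reversal-vs-control comparison.
    """
    params = params or PipelineParams()
    comp1, comp2, comp3 = design.comparisons
    for comparison in (comp1, comp2):
        for g in (comparison.group_a, comparison.group_b):
            if len(design.groups.get(g, [])) < 2:
                raise ValueError(f"group {g!r} needs at least 2 samples")

    m1, dmrs1 = _call(matrix, comp1, params)
    m2, dmrs2 = _call(matrix, comp2, params)
    core_dmrs = _concordant_union(dmrs1, m2, dmrs2, m1, params.concordance_mode)

    gene_map = _map_to_genes(core_dmrs, promoters, params.min_overlap)
    promoter_by_gene = {p.gene_id: p for p in promoters}
    m3 = _prepare(matrix, comp3, params)

    rows = []
    for gene_id in sorted(gene_map):
        promoter = promoter_by_gene[gene_id]
        p1, a1, b1, fc1 = _promoter_stats(m1, comp1, promoter)
        p2, a2, b2, fc2 = _promoter_stats(m2, comp2, promoter)
        significant = (not np.isnan(p1) and p1 < params.alpha) or (
            not np.isnan(p2) and p2 < params.alpha
        )
        if not significant:
            continue
        p3, _, _, fc3 = _promoter_stats(m3, comp3, promoter)
        rows.append(
            {
                "gene_id": gene_id,
                "n_dmrs": len(gene_map[gene_id]),
                "dmr_ids": ",".join(gene_map[gene_id]),
                "p_trt_vs_ctrl": p1,
                "p_trt_vs_rev": p2,
                "p_rev_vs_ctrl": p3,
                "fc_trt_vs_ctrl": fc1,
                "fc_trt_vs_rev": fc2,
                "fc_rev_vs_ctrl": fc3,
                "mean_trt": a1,
                "mean_ctrl": b1,
                "direction": "hyper" if a1 > b1 else "hypo",
            }
        )
    core_genes = pd.DataFrame(
        rows,
        columns=[
            "gene_id", "n_dmrs", "dmr_ids",
            "p_trt_vs_ctrl", "p_trt_vs_rev", "p_rev_vs_ctrl",
            "fc_trt_vs_ctrl", "fc_trt_vs_rev", "fc_rev_vs_ctrl",
            "mean_trt", "mean_ctrl", "direction",
        ],
    )
    logger.info("core panel: %d DMRs -> %d genes", len(core_dmrs), len(core_genes))

    reversible, retained = classify_reversibility(
        core_genes, matrix, design, alpha=params.alpha, params=params
    )
    status = ["reversible" if g in reversible else "retained" for g in core_genes["gene_id"]]
    core_genes = core_genes.assign(status=status)
    return PanelResult(
        dmr_sets={comp1.name: dmrs1, comp2.name: dmrs2},
        core_dmrs=core_dmrs,
        core_genes=core_genes,
        reversible_genes=reversible,
        retained_genes=retained,
    )


def classify_reversibility(
    core_genes: pd.DataFrame | Sequence[str],
    matrix: MethylationMatrix,
    design: StudyDesign,
    alpha: float = 0.05,
    params: PipelineParams | None = None,
    promoters: Sequence[Promoter] | None = None,
) -> tuple[set[str], set[str]]:
    """Partition panel genes into reversible and retained.

    A gene is reversible when its promoter methylation is comparable between
    the reversal and control groups (Mann-Whitney P > alpha); otherwise the
    change is retained after diet normalization.  When ``core_genes`` is the
    frame produced by run_core_panel, its precomputed reversal-vs-control P
    is used; otherwise promoters must be supplied for recomputation.
    """
    params = params or PipelineParams()
    comp3 = design.comparisons[2]
    if isinstance(core_genes, pd.DataFrame):
        gene_p = dict(zip(core_genes["gene_id"], core_genes["p_rev_vs_ctrl"]))
    else:
        if promoters is None:
            raise ValueError("promoters required when passing bare gene ids")
        m3 = _prepare(matrix, comp3, params)
        by_gene = {p.gene_id: p for p in promoters}
        gene_p = {
            g: _promoter_stats(m3, comp3, by_gene[g])[0] for g in core_genes
        }
    reversible = {g for g, p in gene_p.items() if np.isnan(p) or p > alpha}
    retained = set(gene_p) - reversible
    return reversible, retained


def run_persistence_panel(
    matrix: MethylationMatrix,
    promoters: Sequence[Promoter],
    design: StudyDesign,
    params: PipelineParams | None = None,
) -> pd.DataFrame:
    """Genes whose diet-induced methylation change persists after reversal.

    DMRs of treatment-vs-control and reversal-vs-control are cross-checked
    for concordance; genes of the concordant union qualify when the promoter
    differs from control in either comparison (P < alpha) while treatment
    and reversal are equivalent (P >= equivalence_alpha).
    """
    params = params or PipelineParams()
    comp1, comp2, comp3 = design.comparisons
    m1, dmrs1 = _call(matrix, comp1, params)
    m3, dmrs3 = _call(matrix, comp3, params)
    union = _concordant_union(dmrs1, m3, dmrs3, m1, params.concordance_mode)

    gene_map = _map_to_genes(union, promoters, params.min_overlap)
    promoter_by_gene = {p.gene_id: p for p in promoters}
    m2 = _prepare(matrix, comp2, params)

    rows = []
    for gene_id in sorted(gene_map):
        promoter = promoter_by_gene[gene_id]
        p1, _, _, fc1 = _promoter_stats(m1, comp1, promoter)
        p3, _, _, fc3 = _promoter_stats(m3, comp3, promoter)
        p2, _, _, _ = _promoter_stats(m2, comp2, promoter)
        dm_vs_ctrl = (not np.isnan(p1) and p1 < params.alpha) or (
            not np.isnan(p3) and p3 < params.alpha
        )
        equivalent = np.isnan(p2) or p2 >= params.equivalence_alpha
        if dm_vs_ctrl and equivalent:
            rows.append(
                {
                    "gene_id": gene_id,
                    "n_dmrs": len(gene_map[gene_id]),
                    "dmr_ids": ",".join(gene_map[gene_id]),
                    "p_trt_vs_ctrl": p1,
                    "p_rev_vs_ctrl": p3,
                    "p_trt_vs_rev": p2,
                    "fc_trt_vs_ctrl": fc1,
                    "fc_rev_vs_ctrl": fc3,
                }
            )
    out = pd.DataFrame(
        rows,
        columns=[
            "gene_id", "n_dmrs", "dmr_ids",
            "p_trt_vs_ctrl", "p_rev_vs_ctrl", "p_trt_vs_rev",
            "fc_trt_vs_ctrl", "fc_rev_vs_ctrl",
        ],
    )
    logger.info("persistence panel: %d genes", len(out))
    return out


def run_pipeline(
    matrix: MethylationMatrix,
    promoters: Sequence[Promoter],
    design: StudyDesign,
    params: PipelineParams | None = None,
    out_dir: str | Path | None = None,
) -> PanelResult:
    """Full analysis: per-comparison DMRs/DMGs, core panel, persistence panel.

    Deterministic given matrix and parameters; when ``out_dir`` is given, all
    result tables are written as TSVs with a stable column order.
    """
    params = params or PipelineParams()
    result = run_core_panel(matrix, promoters, design, params)
    result.persistent_genes = run_persistence_panel(matrix, promoters, design, params)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, callset in result.dmr_sets.items():
            tag = name.replace(" ", "_").replace("/", "")
            write_table(dmrs_to_bed(callset), out / f"dmrs_{tag}.tsv")
            filtered = _prepare(matrix, callset.comparison, params)
            dmgs = call_dmgs(
                callset, promoters, filtered, callset.comparison,
                alpha=params.alpha, min_overlap=params.min_overlap,
            )
            write_table(dmgs_to_table(dmgs), out / f"dmgs_{tag}.tsv")
        core_dmr_set = DmrCallSet(
            comparison=design.comparisons[0],
            dmrs=sorted(result.core_dmrs, key=lambda d: d.dmr_id),
            n_tested=0,
        )
        write_table(dmrs_to_bed(core_dmr_set), out / "core_dmrs.tsv")
        write_table(result.core_genes, out / "core_genes.tsv")
        write_table(result.persistent_genes, out / "persistent_genes.tsv")
    return result
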