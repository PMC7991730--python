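"""Synthetic study generator: bisulfite counts, phenotypes and qPCR tables
with the statistical structure the analysis assumes, plus a ground-truth
table so every caller's precision and recall can be measured.

The methylome model is beta-binomial: each promoter carries a cluster of
CpGs whose baseline levels scatter around a cluster mean drawn from a Beta
prior; each sample's per-CpG success probability is drawn from a Beta
around the (group-shifted) baseline with configurable concentration, and
methylated counts are binomial at a negative-binomial read depth.  Three
effect patterns are planted: null, reversible (methylation shift in the
FFC group only), and persistent (equal shift in FFC and FFC/SD, so the
change survives diet reversal).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import (
    CpGCallSet,
    PhenotypeTable,
    Promoter,
    build_promoters,
    write_methylation_calls,
    write_promoter_bed,
    write_table,
)

__all__ = [
    "SimulationConfig",
    "TruthTable",
    "simulate_methylome",
    "simulate_phenotypes",
    "simulate_qpcr",
    "write_simulation",
]

#: per-phenotype per-group Normal(location, scale); locations are the study's
#: group medians, scales the IQR-matched normal sd (IQR / 1.349).
PHENOTYPE_MODEL: dict[str, dict[str, tuple[float, float]]] = {
    "BW":   {"SD": (39.5, 1.9),  "FFC/SD": (55.0, 4.8),  "FFC": (79.0, 3.0)},
    "TBF":  {"SD": (27.65, 2.0), "FFC/SD": (48.1, 4.4),  "FFC": (64.8, 3.1)},
    "TC":   {"SD": (1.70, 0.30), "FFC/SD": (1.87, 0.33), "FFC": (12.37, 3.2)},
    "TG":   {"SD": (0.34, 0.04), "FFC/SD": (0.39, 0.09), "FFC": (0.82, 0.40)},
    "GLU":  {"SD": (3.48, 0.25), "FFC/SD": (3.72, 0.30), "FFC": (3.75, 0.22)},
    "LW":   {"SD": (0.51, 0.07), "FFC/SD": (0.73, 0.08), "FFC": (2.15, 0.87)},
    "GLC":  {"SD": (15.3, 20.4), "FFC/SD": (11.77, 12.0), "FFC": (20.19, 9.9)},
    "LTG":  {"SD": (12.23, 3.6), "FFC/SD": (14.14, 4.0), "FFC": (13.70, 3.9)},
    "CHOL": {"SD": (3.51, 0.16), "FFC/SD": (3.58, 0.33), "FFC": (18.23, 8.9)},
}

#: default qPCR truth: one strongly down-regulated target in the FFC group,
#: one up-regulated in both diet-exposed groups, one null target, plus flat
#: reference genes.  Ratios are linear expression multiples vs the SD group.
DEFAULT_QPCR_TRUTH: dict[str, dict[str, float]] = {
    "TGT_DOWN4": {"FFC": 0.25},
    "TGT_UP2": {"FFC": 2.0, "FFC/SD": 2.0},
    "TGT_NULL": {},
}


@dataclass
class SimulationConfig:
    """Study-scale generator settings; defaults mirror the minipig design."""

    seed: int = 0
    n_genes: int = 200
    cpgs_per_promoter: tuple[int, int] = (8, 15)
    cpg_spacing: tuple[int, int] = (20, 150)  # bp between adjacent CpGs
    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"SD": 7, "FFC/SD": 12, "FFC": 10}
    )
    depth_mean: float = 30.0
    depth_dispersion: float = 8.0  # negative-binomial size parameter
    baseline_beta: tuple[float, float] = (3.0, 2.0)  # null cluster means (mean 0.6)
    planted_baseline_range: tuple[float, float] = (0.30, 0.65)
    cpg_concentration: float = 50.0  # scatter of CpG baselines within a cluster
    sample_concentration: float = 100.0  # beta-binomial overdispersion per sample
    frac_reversible: float = 0.10
    frac_persistent: float = 0.05
    delta: float = 0.25  # planted group shift in methylation level
    planted_fraction_of_cpgs: float = 0.7  # run length of the planted DMR
    missing_rate: dict[str, float] | float = 0.05  # per-group zero-depth rate
    min_depth: int = 4  # used only for truth bookkeeping of common sites
    linked_genes: dict[str, tuple[str, float, float, float]] = field(
        default_factory=dict
    )  # gene -> (phenotype, intercept, slope, noise sd)
    qpcr_truth: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_QPCR_TRUTH.items()}
    )
    qpcr_sigma_log2: float = 0.2
    qpcr_sample_scale_sigma_log2: float = 0.15
    reference_genes: tuple[str, ...] = ("TBP", "ACTB")

    def __post_init__(self) -> None:
        if self.frac_reversible + self.frac_persistent > 1:
            raise ValueError("effect fractions exceed 1")
        lo, hi = self.planted_baseline_range
        if not (lo - self.delta >= 0.01 and hi + self.delta <= 0.99):
            raise ValueError(
                "planted baseline range and delta leave no room inside [0.01, 0.99]"
            )

    def sample_ids(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for label, n in self.group_sizes.items():
            tag = label.replace("/", "")
            out[label] = [f"{tag}_{i + 1:02d}" for i in range(n)]
        return out


@dataclass
class TruthTable:
    """Planted ground truth: per-gene effect pattern and DMR interval, plus
    coverage bookkeeping for the common-site count."""

    genes: pd.DataFrame  # gene_id, pattern, delta, direction, dmr_start, dmr_end, n_dmr_cpgs
    n_common_sites: int

    def pattern(self, gene_id: str) -> str:
        return self.genes.set_index("gene_id").loc[gene_id, "pattern"]

    def genes_with(self, pattern: str) -> set[str]:
        return set(self.genes.loc[self.genes["pattern"] == pattern, "gene_id"])

    @property
    def affected_genes(self) -> set[str]:
        return self.genes_with("reversible") | self.genes_with("persistent")


def _group_shift(pattern: str, group: str, delta_signed: float) -> float:
    """Planted methylation shift of one group relative to the SD baseline."""
    if pattern == "reversible":
        return delta_signed if group == "FFC" else 0.0
    if pattern == "persistent":
        return delta_signed if group in ("FFC", "FFC/SD") else 0.0
    return 0.0


def simulate_methylome(
    config: SimulationConfig,
) -> tuple[dict[str, CpGCallSet], list[Promoter], TruthTable]:
    """Generate per-sample CpG call sets, promoters, and the truth table.

    Deterministic given ``config.seed``; every sample covers every site
    (missingness is modelled by zeroing read depth, and the 4x floor then
    removes shallow sites downstream).
    """
    rng = np.random.default_rng(config.seed)
    sample_ids = config.sample_ids()
    samples = [(s, label) for label, ids in sample_ids.items() for s in ids]

    n_rev = round(config.frac_reversible * config.n_genes)
    n_per = round(config.frac_persistent * config.n_genes)
    patterns = ["reversible"] * n_rev + ["persistent"] * n_per
    patterns += ["null"] * (config.n_genes - len(patterns))
    patterns = list(rng.permutation(patterns))

    if isinstance(config.missing_rate, Mapping):
        missing_rate = dict(config.missing_rate)
    else:
        missing_rate = {label: float(config.missing_rate) for label in sample_ids}

    tss_rows = []
    truth_rows = []
    chrom = "chr1"
    all_pos: list[np.ndarray] = []
    all_m: list[np.ndarray] = []  # per-gene (n_cpgs, n_samples) mean levels
    for g in range(config.n_genes):
        gene_id = f"gene_{g + 1:04d}"
        tss = 1_000_000 + g * 10_000
        tss_rows.append((gene_id, chrom, "+", tss))
        pattern = patterns[g]

        k = int(rng.integers(config.cpgs_per_promoter[0], config.cpgs_per_promoter[1] + 1))
        spacing = rng.integers(config.cpg_spacing[0], config.cpg_spacing[1] + 1, size=k)
        pos = tss - 2000 + np.cumsum(spacing)
        all_pos.append(pos)

        if pattern == "null":
            cluster_mean = float(rng.beta(*config.baseline_beta))
            cluster_mean = min(max(cluster_mean, 0.02), 0.98)
        else:
            lo, hi = config.planted_baseline_range
            cluster_mean = float(rng.uniform(lo, hi))
        conc = config.cpg_concentration
        baseline = rng.beta(cluster_mean * conc, (1 - cluster_mean) * conc, size=k)
        baseline = np.clip(baseline, 0.01, 0.99)

        if pattern == "null":
            delta_signed = 0.0
            dmr_lo, dmr_hi, run = 0, 0, 0
        else:
            direction = 1.0 if rng.random() < 0.5 else -1.0
            delta_signed = direction * config.delta
            run = max(5, int(np.ceil(config.planted_fraction_of_cpgs * k)))
            run = min(run, k)
            offset = int(rng.integers(0, k - run + 1))
            dmr_lo, dmr_hi = int(pos[offset]), int(pos[offset + run - 1]) + 1
        effect_mask = np.zeros(k, dtype=bool)
        if pattern != "null":
            effect_mask[offset : offset + run] = True

        m = np.empty((k, len(samples)))
        for j, (_, label) in enumerate(samples):
            shift = _group_shift(pattern, label, delta_signed)
            m[:, j] = np.clip(baseline + shift * effect_mask, 0.01, 0.99)
        all_m.append(m)
        truth_rows.append(
            {
                "gene_id": gene_id,
                "pattern": pattern,
                "delta": delta_signed,
                "direction": "hyper" if delta_signed > 0 else ("hypo" if delta_signed < 0 else "."),
                "dmr_start": dmr_lo,
                "dmr_end": dmr_hi,
                "n_dmr_cpgs": run,
            }
        )

    pos_all = np.concatenate(all_pos)
    m_all = np.vstack(all_m)  # (n_sites, n_samples)
    n_sites, n_samples = m_all.shape

    nb_n = config.depth_dispersion
    nb_p = nb_n / (nb_n + config.depth_mean)
    depth = rng.negative_binomial(nb_n, nb_p, size=(n_sites, n_samples))
    for j, (_, label) in enumerate(samples):
        drop = rng.random(n_sites) < missing_rate[label]
        depth[drop, j] = 0
    nu = config.sample_concentration
    p = rng.beta(m_all * nu, (1 - m_all) * nu)
    meth = rng.binomial(depth, p)

    callsets: dict[str, CpGCallSet] = {}
    for j, (sample, _) in enumerate(samples):
        covered = depth[:, j] > 0
        df = pd.DataFrame(
            {
                "chrom": chrom,
                "pos": pos_all[covered],
                "meth_count": meth[covered, j],
                "total_count": depth[covered, j],
            }
        )
        callsets[sample] = CpGCallSet.from_dataframe(sample, df)

    promoters = build_promoters(
        pd.DataFrame(tss_rows, columns=["gene_id", "chrom", "strand", "tss"])
    )
    n_common = int(((depth >= config.min_depth).all(axis=1)).sum())
    truth = TruthTable(genes=pd.DataFrame(truth_rows), n_common_sites=n_common)
    return callsets, promoters, truth


def simulate_phenotypes(
    config: SimulationConfig,
    groups: Mapping[str, str],
    promoter_levels: pd.DataFrame | None = None,
    rng: np.random.Generator | None = None,
) -> PhenotypeTable:
    """Draw per-group phenotypes from the study-calibrated normal model.

    ``groups`` maps sample id to diet group.  For genes listed in
    ``config.linked_genes`` the named phenotype is instead generated as
    intercept + slope * promoter methylation + noise (per sample), planting
    a recoverable correlation; this requires ``promoter_levels`` (genes x
    samples).  Liver-content phenotypes are clipped at 0.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    samples = list(groups)
    data = {"group": [groups[s] for s in samples]}
    for pheno, model in PHENOTYPE_MODEL.items():
        values = []
        for s in samples:
            loc, scale = model[groups[s]]
            values.append(loc + scale * rng.standard_normal())
        data[pheno] = np.maximum(np.asarray(values), 0.0)
    df = pd.DataFrame(data, index=pd.Index(samples, name="sample_id"))
    for gene, (pheno, intercept, slope, noise_sd) in config.linked_genes.items():
        if promoter_levels is None or gene not in promoter_levels.index:
            raise ValueError(f"linked gene {gene!r} requires promoter_levels")
        levels = promoter_levels.loc[gene].reindex(samples)
        df[pheno] = (
            intercept + slope * levels + noise_sd * rng.standard_normal(len(samples))
        ).to_numpy()
    return PhenotypeTable(data=df)


def simulate_qpcr(
    config: SimulationConfig,
    groups: Mapping[str, str] | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Generate a qPCR Cq table with planted group fold changes.

    Expression is lognormal around the group mean fixed by the planted
    ratios (vs the SD group); reference genes have no group effect.  A
    per-sample global scale factor emulates input-amount variation and is
    removed by reference normalization.  Cq = cq0 - log_E(expression).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    if groups is None:
        groups = {
            s: label for label, ids in config.sample_ids().items() for s in ids
        }
    samples = list(groups)
    sample_scale = config.qpcr_sample_scale_sigma_log2 * rng.standard_normal(len(samples))
    genes = list(config.qpcr_truth) + list(config.reference_genes)
    rows = []
    for gene in genes:
        ratios = config.qpcr_truth.get(gene, {})
        efficiency = float(rng.uniform(1.85, 2.0))
        cq0 = float(rng.uniform(20.0, 26.0))
        for i, s in enumerate(samples):
            ratio = float(ratios.get(groups[s], 1.0))
            log2_expr = (
                np.log2(ratio)
                + sample_scale[i]
                + config.qpcr_sigma_log2 * rng.standard_normal()
            )
            expr = 2.0 ** log2_expr
            cq = cq0 - np.log(expr) / np.log(efficiency)
            rows.append({"gene": gene, "sample_id": s, "cq": cq, "efficiency": efficiency})
    return pd.DataFrame(rows)


def write_simulation(config: SimulationConfig, out_dir: str | Path) -> None:
    """Write a full synthetic study: bismark-coverage files (one per sample),
    promoters BED, phenotypes TSV, qPCR TSV, and the truth table TSV."""
    out = Path(out_dir)
    (out / "calls").mkdir(parents=True, exist_ok=True)
    callsets, promoters, truth = simulate_methylome(config)
    for sample, cs in callsets.items():
        write_methylation_calls(cs, out / "calls" / f"{sample}.cov", "bismark_cov")
    write_promoter_bed(promoters, out / "promoters.bed")
    groups = {s: label for label, ids in config.sample_ids().items() for s in ids}
    pheno = simulate_phenotypes(config, groups)
    write_table(pheno.data.reset_index(), out / "phenotypes.tsv")
    write_table(simulate_qpcr(config, groups), out / "qpcr.tsv")
    write_table(truth.genes, out / "truth_genes.tsv")
    write_table(
        pd.DataFrame({"n_common_sites": [truth.n_common_sites]}),
        out / "truth_summary.tsv",
    )
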