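"""Phenotype-methylation correlation screening, PCA on common CpG sites,
chi-square variability ranking, and hierarchical clustering support."""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from sklearn.decomposition import PCA

from .core_io import PhenotypeTable, Promoter
from .quant import MethylationMatrix

__all__ = [
    "CorrelationRecord",
    "correlate_panel",
    "pca_common_sites",
    "chi2_rank_promoters",
    "promoter_mean_table",
    "cluster_promoters",
]

DEFAULT_PHENOS = ("BW", "TBF", "TC", "TG", "GLU", "LW", "GLC", "LTG", "CHOL")


@dataclass(frozen=True)
class CorrelationRecord:
    gene_id: str
    phenotype: str
    r: float
    p: float
    tier: str  # none / assoc / strong


def _tier(r: float, p: float, rule: str = "and") -> str:
    """Assign the association tier from the screening thresholds.

    Tiers: "strong" at P <= 0.001 with r >= 0.6, "assoc" at P <= 0.01 with
    |r| >= 0.4.  The default combines each pair of thresholds conjunctively;
    ``rule='or'`` gives the disjunctive reading.
    """
    if np.isnan(r) or np.isnan(p):
        return "none"
    if rule == "and":
        if p <= 0.001 and r >= 0.6:
            return "strong"
        if p <= 0.01 and abs(r) >= 0.4:
            return "assoc"
    elif rule == "or":
        if p <= 0.001 or r >= 0.6:
            return "strong"
        if p <= 0.01 or abs(r) >= 0.4:
            return "assoc"
    else:
        raise ValueError(f"unknown rule {rule!r}")
    return "none"


def correlate_panel(
    matrix: MethylationMatrix,
    panel_genes: Sequence[str],
    promoters: Sequence[Promoter],
    phenotypes: PhenotypeTable,
    phenos: Sequence[str] = DEFAULT_PHENOS,
    rule: str = "and",
) -> list[CorrelationRecord]:
    """Pearson correlation of promoter methylation with each phenotype.

    For each panel gene the per-sample depth-weighted promoter level is
    correlated with each phenotype across all samples with both values
    (two-sided P from the t distribution, df = n - 2).  Constant input
    yields a record with missing r.
    """
    by_gene = {p.gene_id: p for p in promoters}
    records: list[CorrelationRecord] = []
    for gene_id in panel_genes:
        promoter = by_gene[gene_id]
        sites = matrix.sites_in(promoter.chrom, promoter.start, promoter.end)
        levels = pd.Series(
            matrix.region_levels(sites) if sites.size else np.nan,
            index=matrix.samples,
        )
        for pheno in phenos:
            if pheno not in phenotypes.data.columns:
                continue
            values = phenotypes.data[pheno].reindex(levels.index)
            ok = levels.notna() & values.notna()
            x = levels[ok].to_numpy(dtype=float)
            y = values[ok].to_numpy(dtype=float)
            if x.size < 3 or np.unique(x).size == 1 or np.unique(y).size == 1:
                records.append(CorrelationRecord(gene_id, pheno, np.nan, np.nan, "none"))
                continue
            res = stats.pearsonr(x, y)
            r, p = float(res.statistic), float(res.pvalue)
            records.append(CorrelationRecord(gene_id, pheno, r, p, _tier(r, p, rule)))
    return records


def correlation_table(records: Sequence[CorrelationRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in records],
            "phenotype": [r.phenotype for r in records],
            "r": [r.r for r in records],
            "p": [r.p for r in records],
            "tier": [r.tier for r in records],
        }
    )


def pca_common_sites(matrix: MethylationMatrix, n_components: int = 2):
    """Centered (unscaled) PCA of samples over the common-site ratios.

    Returns (scores DataFrame indexed by sample with a group column,
    explained variance ratio).  Component signs follow a deterministic
    convention: the coordinate with the largest |loading| is made positive.
    """
    common = matrix.common_view()
    if common.n_sites == 0:
        raise ValueError("common view is empty")
    if len(common.samples) < 2:
        raise ValueError("need at least 2 samples")
    X = common.ratio.T  # samples x sites
    n_components = min(n_components, min(X.shape) - 1) or 1
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    for k in range(n_components):  # deterministic sign convention
        j = int(np.argmax(np.abs(pca.components_[k])))
        if pca.components_[k, j] < 0:
            pca.components_[k] *= -1
            scores[:, k] *= -1
    df = pd.DataFrame(
        scores,
        index=common.samples,
        columns=[f"PC{k + 1}" for k in range(n_components)],
    )
    df["group"] = [common.groups[s] for s in common.samples]
    return df, pca.explained_variance_ratio_


def chi2_rank_promoters(
    matrix: MethylationMatrix,
    promoters: Sequence[Promoter],
    design_groups: Sequence[str] | None = None,
    top_k: int = 1000,
) -> pd.DataFrame:
    """Rank promoters by methylation variability across diet groups.

    For each promoter the methylated and unmethylated read depths are pooled
    per group into a groups x 2 contingency table and tested with the
    chi-square test (no continuity correction); promoters are ranked by
    ascending P.  Promoters with zero pooled depth in any group are skipped.
    """
    if design_groups is None:
        design_groups = list(dict.fromkeys(matrix.groups))
    if len(design_groups) < 2:
        raise ValueError("need at least 2 groups")
    cols = {g: matrix.sample_indices(g) for g in design_groups}
    ok_depth = matrix.depth * (matrix.depth >= matrix.min_depth)
    ok_meth = matrix.meth * (matrix.depth >= matrix.min_depth)
    rows = []
    for promoter in promoters:
        sites = matrix.sites_in(promoter.chrom, promoter.start, promoter.end)
        if sites.size == 0:
            continue
        table = []
        skip = False
        for g in design_groups:
            total = int(ok_depth[np.ix_(sites, cols[g])].sum())
            meth = int(ok_meth[np.ix_(sites, cols[g])].sum())
            if total == 0:
                skip = True
                break
            table.append([meth, total - meth])
        if skip:
            continue
        arr = np.asarray(table)
        if arr[:, 0].sum() == 0 or arr[:, 1].sum() == 0:
            stat, p = 0.0, 1.0  # degenerate margin: no variability signal
        else:
            stat, p, _, _ = stats.chi2_contingency(arr, correction=False)
        rows.append({"gene_id": promoter.gene_id, "chi2": float(stat), "p": float(p)})
    ranked = (
        pd.DataFrame(rows, columns=["gene_id", "chi2", "p"])
        .sort_values(["p", "gene_id"], ascending=[True, True], kind="mergesort")
        .reset_index(drop=True)
    )
    return ranked.head(top_k)


def promoter_mean_table(
    matrix: MethylationMatrix,
    promoters: Sequence[Promoter],
    genes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-sample promoter methylation levels (genes x samples)."""
    wanted = set(genes) if genes is not None else None
    rows, index = [], []
    for promoter in promoters:
        if wanted is not None and promoter.gene_id not in wanted:
            continue
        sites = matrix.sites_in(promoter.chrom, promoter.start, promoter.end)
        if sites.size == 0:
            continue
        rows.append(matrix.region_levels(sites))
        index.append(promoter.gene_id)
    return pd.DataFrame(rows, index=index, columns=matrix.samples)


def cluster_promoters(levels: pd.DataFrame, method: str = "average"):
    """Hierarchical clustering of promoter methylation rows (average linkage
    on Euclidean distance); returns the scipy linkage matrix."""
    X = levels.to_numpy(dtype=float)
    row_means = np.nanmean(X, axis=1, keepdims=True)
    X = np.where(np.isnan(X), row_means, X)
    return hierarchy.linkage(X, method=method, metric="euclidean")
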