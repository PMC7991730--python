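"""Efficiency-corrected qPCR relative quantification and differential
expression calls.

Quantities follow the standard relative-quantification workflow: per gene,
Cq values are converted to relative quantities with the gene's amplification
efficiency (RQ = E^(min Cq - Cq), so the best-expressed sample has RQ = 1);
each sample's target RQs are then divided by the geometric mean of the
reference-gene RQs (TBP and ACTB by default).  Group comparisons run a
two-sided t-test on log2 normalized quantities with Benjamini-Hochberg
adjustment across genes; a gene is differentially expressed when
|signed FC| > 1.5 and adjusted P < 0.05.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_io import Comparison
from .dmg import fold_change

__all__ = [
    "read_qpcr",
    "relative_quantity",
    "rq_table",
    "normalize",
    "de_test",
]

DEFAULT_REFERENCES = ("TBP", "ACTB")


def read_qpcr(path: str | Path) -> pd.DataFrame:
    """Read a qPCR TSV with columns gene, sample_id, cq, efficiency."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "sample_id", "cq", "efficiency"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def relative_quantity(cq: float, efficiency: float, cq_ref_point: float) -> float:
    """RQ = efficiency^(cq_ref_point - cq); the reference-point sample has RQ 1."""
    if not 1.0 < efficiency <= 2.0:
        raise ValueError(f"efficiency must be in (1, 2], got {efficiency}")
    return float(efficiency ** (cq_ref_point - cq))


def rq_table(measurements: pd.DataFrame) -> pd.DataFrame:
    """Relative quantities per gene and sample (samples x genes).

    The reference point of each gene is its minimum Cq across samples.
    Downstream normalization and fold changes are invariant to this choice.
    """
    out = measurements.copy()
    out["rq"] = np.nan
    for gene, sub in measurements.groupby("gene"):
        cq_min = float(sub["cq"].min())
        out.loc[sub.index, "rq"] = [
            relative_quantity(row.cq, row.efficiency, cq_min)
            for row in sub.itertuples()
        ]
    return out.pivot_table(index="sample_id", columns="gene", values="rq")


def normalize(
    rq: pd.DataFrame, reference_genes: Sequence[str] = DEFAULT_REFERENCES
) -> pd.DataFrame:
    """Divide each sample's target RQs by the geometric mean of its
    reference-gene RQs; samples missing a reference are dropped (warning)."""
    missing_ref = [g for g in reference_genes if g not in rq.columns]
    if missing_ref:
        raise ValueError(f"reference gene(s) not measured: {missing_ref}")
    refs = rq[list(reference_genes)]
    ok = refs.notna().all(axis=1)
    if not ok.all():
        warnings.warn(
            f"{int((~ok).sum())} sample(s) missing a reference gene, dropped"
        )
    kept = rq.loc[ok]
    norm_factor = np.exp(np.log(kept[list(reference_genes)]).mean(axis=1))
    targets = [g for g in kept.columns if g not in reference_genes]
    return kept[targets].div(norm_factor, axis=0)


def de_test(
    normalized: pd.DataFrame,
    groups: Mapping[str, str],
    comparison: Comparison,
    fc_threshold: float = 1.5,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene differential expression between two groups.

    Signed fold change is computed from the group means of normalized RQ;
    the test is a two-sided Welch t-test on log2 quantities, BH-adjusted
    across genes.  A gene is DE when |fc| > fc_threshold (strict) and
    adjusted P < alpha.
    """
    labels = pd.Series({s: groups[s] for s in normalized.index})
    ia = labels[labels == comparison.group_a].index
    ib = labels[labels == comparison.group_b].index
    if min(len(ia), len(ib)) < 2:
        raise ValueError("need at least 2 samples per group")
    rows = []
    for gene in normalized.columns:
        xa = normalized.loc[ia, gene].dropna()
        xb = normalized.loc[ib, gene].dropna()
        if (xa <= 0).any() or (xb <= 0).any():
            raise ValueError(f"{gene}: non-positive normalized quantity")
        fc = fold_change(float(xa.mean()), float(xb.mean()))
        t = stats.ttest_ind(np.log2(xa), np.log2(xb), equal_var=False)
        rows.append({"gene": gene, "fc_signed": fc, "p": float(t.pvalue)})
    out = pd.DataFrame(rows)
    out["adj_p"] = multipletests(out["p"], method="fdr_bh")[1]
    out["is_de"] = (out["fc_signed"].abs() > fc_threshold) & (out["adj_p"] < alpha)
    return out
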