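"""Per-site and per-region methylation levels and the sites x samples matrix.

Two averaging conventions coexist on purpose: within a sample, a region's
level is the depth-weighted ratio sum(meth)/sum(total) over its qualifying
CpGs; across samples, group means are unweighted (each animal counts once).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import Comparison, CpGCall, CpGCallSet

__all__ = [
    "MethylationMatrix",
    "site_level",
    "region_level",
    "build_matrix",
    "filter_missing_by_group",
    "group_mean",
    "matrix_to_tsv",
    "matrix_from_tsv",
]


def site_level(call: CpGCall, min_depth: int = 4) -> float:
    """Methylation level of one CpG: meth/total, or NaN below the depth floor."""
    if call.total_count < min_depth:
        return float("nan")
    return call.meth_count / call.total_count


def region_level(calls: Iterable[CpGCall], min_depth: int = 4) -> float:
    """Depth-weighted region level: sum(meth)/sum(total) over CpGs with
    total >= min_depth; NaN when no CpG qualifies."""
    meth = total = 0
    for c in calls:
        if c.total_count >= min_depth:
            meth += c.meth_count
            total += c.total_count
    return meth / total if total > 0 else float("nan")


@dataclass
class MethylationMatrix:
    """Sites x samples methylation counts with a coverage-derived mask.

    A ratio is present exactly where depth >= min_depth; elsewhere it is NaN.
    ``sites`` has columns chrom, pos (sorted); ``meth`` and ``depth`` are
    integer arrays of shape (n_sites, n_samples).
    """

    sites: pd.DataFrame
    samples: list[str]
    groups: pd.Series  # sample id -> group label
    meth: np.ndarray
    depth: np.ndarray
    min_depth: int = 4

    def __post_init__(self) -> None:
        if self.meth.shape != self.depth.shape:
            raise ValueError("meth and depth shapes differ")
        if self.meth.shape != (len(self.sites), len(self.samples)):
            raise ValueError("matrix shape does not match sites/samples")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def ratio(self) -> np.ndarray:
        """Methylation ratios with NaN where depth < min_depth."""
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(
                self.depth >= self.min_depth,
                self.meth / np.maximum(self.depth, 1),
                np.nan,
            )
        return r

    def sample_indices(self, group: str) -> np.ndarray:
        mask = np.array([self.groups[s] == group for s in self.samples])
        return np.flatnonzero(mask)

    def select_sites(self, index: np.ndarray) -> "MethylationMatrix":
        return replace(
            self,
            sites=self.sites.iloc[index].reset_index(drop=True),
            meth=self.meth[index],
            depth=self.depth[index],
        )

    def common_view(self) -> "MethylationMatrix":
        """Sites observed (depth >= min_depth) in every sample."""
        keep = np.flatnonzero((self.depth >= self.min_depth).all(axis=1))
        return self.select_sites(keep)

    def sites_in(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Indices of sites with the given chrom and start <= pos < end."""
        on = self.sites["chrom"].to_numpy() == chrom
        pos = self.sites["pos"].to_numpy()
        return np.flatnonzero(on & (pos >= start) & (pos < end))

    def region_levels(self, site_index: np.ndarray) -> np.ndarray:
        """Per-sample depth-weighted region levels over the given sites."""
        d = self.depth[site_index]
        m = self.meth[site_index]
        ok = d >= self.min_depth
        total = np.where(ok, d, 0).sum(axis=0)
        meth = np.where(ok, m, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(total > 0, meth / np.maximum(total, 1), np.nan)


def build_matrix(
    callsets: Sequence[CpGCallSet] | Mapping[str, CpGCallSet],
    groups: Mapping[str, str],
    min_depth: int = 4,
) -> MethylationMatrix:
    """Assemble the site-union matrix across samples.

    The site universe is the union of all samples' sites; coverage below
    min_depth (or an absent site) leaves the ratio missing.  The matrix's
    ``common_view`` then selects sites observed in every sample.
    """
    if isinstance(callsets, Mapping):
        callsets = list(callsets.values())
    if len(callsets) < 2:
        raise ValueError("need at least 2 samples")
    for cs in callsets:
        if len(cs) == 0:
            raise ValueError(f"sample {cs.sample_id} has zero sites")
        if cs.sample_id not in groups:
            raise ValueError(f"sample {cs.sample_id} has no group label")

    samples = [cs.sample_id for cs in callsets]
    union = (
        pd.concat([cs.calls[["chrom", "pos"]] for cs in callsets])
        .drop_duplicates()
        .sort_values(["chrom", "pos"], kind="mergesort")
        .reset_index(drop=True)
    )
    key = pd.MultiIndex.from_frame(union)
    n_sites = len(union)
    meth = np.zeros((n_sites, len(samples)), dtype=np.int64)
    depth = np.zeros((n_sites, len(samples)), dtype=np.int64)
    for j, cs in enumerate(callsets):
        idx = key.get_indexer(pd.MultiIndex.from_frame(cs.calls[["chrom", "pos"]]))
        meth[idx, j] = cs.calls["meth_count"].to_numpy()
        depth[idx, j] = cs.calls["total_count"].to_numpy()
    return MethylationMatrix(
        sites=union,
        samples=samples,
        groups=pd.Series({s: groups[s] for s in samples}),
        meth=meth,
        depth=depth,
        min_depth=min_depth,
    )


def filter_missing_by_group(
    matrix: MethylationMatrix,
    comparison: Comparison,
    max_missing_frac: float = 0.3,
    scope: str = "comparison",
) -> MethylationMatrix:
    """Drop sites whose missing fraction exceeds max_missing_frac in any group.

    ``scope='comparison'`` (default) checks the two groups of the comparison;
    ``scope='all_groups'`` checks every group in the design.  The inequality
    is strict: a missing fraction of exactly 0.30 is retained.
    """
    if scope == "comparison":
        labels = [comparison.group_a, comparison.group_b]
    elif scope == "all_groups":
        labels = list(dict.fromkeys(matrix.groups))
    else:
        raise ValueError(f"unknown scope {scope!r}")
    missing = matrix.depth < matrix.min_depth
    keep = np.ones(matrix.n_sites, dtype=bool)
    for label in labels:
        cols = matrix.sample_indices(label)
        if cols.size == 0:
            raise ValueError(f"group {label!r} has no samples in the matrix")
        frac = missing[:, cols].mean(axis=1)
        keep &= frac <= max_missing_frac
    return matrix.select_sites(np.flatnonzero(keep))


def group_mean(
    matrix: MethylationMatrix,
    sites: int | np.ndarray | Sequence[int],
    group: str,
    region: bool = False,
) -> float:
    """Unweighted group mean over per-sample values at a site or region.

    For a single site the per-sample value is the site ratio; for a region
    (``region=True`` with multiple site indices) it is the depth-weighted
    per-sample region level.  NaN when every sample is missing.
    """
    cols = matrix.sample_indices(group)
    if cols.size == 0:
        raise ValueError(f"group {group!r} has no samples")
    if region:
        values = matrix.region_levels(np.asarray(sites, dtype=int))[cols]
    else:
        values = matrix.ratio[int(np.atleast_1d(sites)[0]), cols]
    if np.all(np.isnan(values)):
        return float("nan")
    return float(np.nanmean(values))


def matrix_to_tsv(matrix: MethylationMatrix, path: str | Path) -> None:
    """Export the ratio matrix: site index column "chrom:pos", one column per
    sample, missing encoded as NA."""
    site_key = (
        matrix.sites["chrom"].astype(str) + ":" + matrix.sites["pos"].astype(str)
    )
    df = pd.DataFrame(matrix.ratio, columns=matrix.samples)
    df.insert(0, "site", site_key.to_numpy())
    df.to_csv(path, sep="\t", index=False, float_format="%.6g", na_rep="NA")


def matrix_from_tsv(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a ratio matrix TSV back as (sites, ratios).

    Counts are not recoverable from ratios, so this returns plain frames for
    site-level analyses rather than a full MethylationMatrix.
    """
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    split = df["site"].str.rsplit(":", n=1, expand=True)
    sites = pd.DataFrame({"chrom": split[0], "pos": split[1].astype(int)})
    return sites, df.drop(columns="site")
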