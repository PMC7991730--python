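"""Domain records and readers/writers for promoter bisulfite methylation data.

Internal coordinates are 0-based half-open throughout.  Bismark-coverage input
is 1-based inclusive and converted on read; the 4-column bedGraph-like count
dialect is already 0-based.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CpGCall",
    "CpGCallSet",
    "Promoter",
    "Comparison",
    "PhenotypeTable",
    "read_methylation_calls",
    "write_methylation_calls",
    "build_promoters",
    "read_tss_table",
    "read_promoter_bed",
    "write_promoter_bed",
    "read_phenotypes",
    "write_table",
]

#: phenotype columns of the minipig study design (units in parentheses):
#: body weight (kg), total body fat (%), total cholesterol (mmol/L),
#: triglycerides (mmol/L), plasma glucose (mmol/L), liver weight (kg),
#: liver glycogen (mg/g), liver triglycerides (mg/g), liver cholesterol (mg/g).
PHENOTYPE_COLUMNS = ("BW", "TBF", "TC", "TG", "GLU", "LW", "GLC", "LTG", "CHOL")

#: diet group labels: standard chow, diet-reversal, high fat/fructose/cholesterol
GROUP_LABELS = ("SD", "FFC/SD", "FFC")


@dataclass(frozen=True)
class CpGCall:
    """One CpG site in one sample: methylated and total read counts."""

    chrom: str
    pos: int  # 0-based coordinate of the cytosine
    meth_count: int
    total_count: int

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError(f"negative position {self.pos}")
        if self.total_count < 1:
            raise ValueError(f"total_count must be >= 1, got {self.total_count}")
        if not 0 <= self.meth_count <= self.total_count:
            raise ValueError(
                f"meth_count {self.meth_count} outside [0, {self.total_count}]"
            )


_CALL_COLUMNS = ["chrom", "pos", "meth_count", "total_count"]


@dataclass
class CpGCallSet:
    """Per-sample CpG methylation calls, sorted by (chrom, pos), deduplicated.

    ``calls`` is a DataFrame with columns chrom, pos, meth_count, total_count.
    """

    sample_id: str
    calls: pd.DataFrame

    @classmethod
    def from_dataframe(cls, sample_id: str, df: pd.DataFrame) -> "CpGCallSet":
        df = df[_CALL_COLUMNS].copy()
        _validate_counts(df)
        df = df.drop_duplicates()
        dup = df.duplicated(subset=["chrom", "pos"], keep=False)
        if dup.any():
            site = df.loc[dup, ["chrom", "pos"]].iloc[0]
            raise ValueError(
                f"sample {sample_id}: conflicting duplicate counts at "
                f"{site['chrom']}:{site['pos']}"
            )
        df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
        return cls(sample_id=sample_id, calls=df)

    @classmethod
    def from_records(cls, sample_id: str, records: Iterable[CpGCall]) -> "CpGCallSet":
        df = pd.DataFrame(
            [(c.chrom, c.pos, c.meth_count, c.total_count) for c in records],
            columns=_CALL_COLUMNS,
        )
        return cls.from_dataframe(sample_id, df)

    def __len__(self) -> int:
        return len(self.calls)

    def __iter__(self):
        for row in self.calls.itertuples(index=False):
            yield CpGCall(row.chrom, int(row.pos), int(row.meth_count), int(row.total_count))


def _validate_counts(df: pd.DataFrame) -> None:
    if (df["total_count"] < 1).any():
        i = int(df.index[df["total_count"] < 1][0])
        raise ValueError(f"row {i}: total_count < 1")
    if (df["meth_count"] < 0).any():
        i = int(df.index[df["meth_count"] < 0][0])
        raise ValueError(f"row {i}: negative meth_count")
    if (df["meth_count"] > df["total_count"]).any():
        i = int(df.index[df["meth_count"] > df["total_count"]][0])
        raise ValueError(f"row {i}: meth_count exceeds total_count")
    if (df["pos"] < 0).any():
        i = int(df.index[df["pos"] < 0][0])
        raise ValueError(f"row {i}: negative position")


def read_methylation_calls(
    path: str | Path, dialect: str = "bismark_cov", sample_id: str | None = None
) -> CpGCallSet:
    """Read per-CpG methylation counts in one of two text dialects.

    ``bismark_cov``: chrom, start (1-based), end, percent methylated,
    methylated count, unmethylated count.  ``bedgraph4``: chrom,
    start (0-based), end, methylated count, total count.

    Positions are normalised to 0-based; exact duplicate rows are collapsed,
    conflicting duplicates raise.
    """
    path = Path(path)
    sample_id = sample_id if sample_id is not None else path.stem.split(".")[0]
    try:
        raw = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty methylation call file") from None

    if dialect == "bismark_cov":
        ncol, names = 6, ["chrom", "start", "end", "pct", "meth", "unmeth"]
    elif dialect == "bedgraph4":
        ncol, names = 5, ["chrom", "start", "end", "meth", "total"]
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if raw.shape[1] != ncol:
        raise ValueError(
            f"{path}: expected {ncol} columns for dialect {dialect!r}, "
            f"got {raw.shape[1]}"
        )
    raw.columns = names
    numeric_cols = [c for c in names if c != "chrom"]
    parsed = raw[numeric_cols].apply(pd.to_numeric, errors="coerce")
    bad = parsed.isna().any(axis=1)
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 1
        raise ValueError(f"{path}: malformed row at line {line}")

    if dialect == "bismark_cov":
        df = pd.DataFrame(
            {
                "chrom": raw["chrom"],
                "pos": parsed["start"].astype(int) - 1,
                "meth_count": parsed["meth"].astype(int),
                "total_count": (parsed["meth"] + parsed["unmeth"]).astype(int),
            }
        )
        if (parsed["unmeth"] < 0).any():
            line = int(np.flatnonzero((parsed["unmeth"] < 0).to_numpy())[0]) + 1
            raise ValueError(f"{path}: negative unmethylated count at line {line}")
    else:
        df = pd.DataFrame(
            {
                "chrom": raw["chrom"],
                "pos": parsed["start"].astype(int),
                "meth_count": parsed["meth"].astype(int),
                "total_count": parsed["total"].astype(int),
            }
        )
    return CpGCallSet.from_dataframe(sample_id, df)


def write_methylation_calls(
    callset: CpGCallSet, path: str | Path, dialect: str = "bismark_cov"
) -> None:
    """Write a call set in the chosen dialect (inverse of the reader)."""
    df = callset.calls
    if dialect == "bismark_cov":
        unmeth = df["total_count"] - df["meth_count"]
        pct = 100.0 * df["meth_count"] / df["total_count"]
        out = pd.DataFrame(
            {
                "chrom": df["chrom"],
                "start": df["pos"] + 1,
                "end": df["pos"] + 1,
                "pct": pct.map(lambda v: f"{v:.6g}"),
                "meth": df["meth_count"],
                "unmeth": unmeth,
            }
        )
    elif dialect == "bedgraph4":
        out = pd.DataFrame(
            {
                "chrom": df["chrom"],
                "start": df["pos"],
                "end": df["pos"] + 1,
                "meth": df["meth_count"],
                "total": df["total_count"],
            }
        )
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    out.to_csv(path, sep="\t", header=False, index=False)


@dataclass(frozen=True)
class Promoter:
    """Strand-aware promoter window around a TSS, 0-based half-open."""

    gene_id: str
    chrom: str
    strand: str
    tss: int
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"unknown strand {self.strand!r}")
        if not self.start < self.end:
            raise ValueError(f"empty promoter interval [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


def build_promoters(
    tss_table: pd.DataFrame | Iterable[tuple],
    upstream: int = 2200,
    downstream: int = 500,
) -> list[Promoter]:
    """Build promoter windows from 2.2 kb upstream to 0.5 kb downstream of
    each TSS (strand-aware; "upstream" means 5' of the gene), clipped at 0.
    """
    if not isinstance(tss_table, pd.DataFrame):
        tss_table = pd.DataFrame(
            list(tss_table), columns=["gene_id", "chrom", "strand", "tss"]
        )
    promoters = []
    for row in tss_table.itertuples(index=False):
        tss = int(row.tss)
        if tss < 0:
            raise ValueError(f"{row.gene_id}: negative TSS {tss}")
        if row.strand == "+":
            start, end = tss - upstream, tss + downstream
        elif row.strand == "-":
            start, end = tss - downstream, tss + upstream
        else:
            raise ValueError(f"{row.gene_id}: unknown strand {row.strand!r}")
        promoters.append(
            Promoter(
                gene_id=str(row.gene_id),
                chrom=str(row.chrom),
                strand=str(row.strand),
                tss=tss,
                start=max(0, start),
                end=end,
            )
        )
    return promoters


def read_tss_table(path: str | Path) -> pd.DataFrame:
    """Read a TSS TSV with header columns gene_id, chrom, strand, tss."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "chrom", "strand", "tss"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def read_promoter_bed(
    path: str | Path, upstream: int = 2200, downstream: int = 500
) -> list[Promoter]:
    """Read promoters from BED6 (chrom, start, end, gene_id, score, strand).

    The TSS is inferred from the window geometry: ``end - downstream`` on the
    plus strand, ``start + downstream`` on the minus strand.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "gene_id", "score", "strand"],
    )
    promoters = []
    for row in df.itertuples(index=False):
        tss = int(row.end) - downstream if row.strand == "+" else int(row.start) + downstream
        promoters.append(
            Promoter(
                gene_id=str(row.gene_id),
                chrom=str(row.chrom),
                strand=str(row.strand),
                tss=tss,
                start=int(row.start),
                end=int(row.end),
            )
        )
    return promoters


def write_promoter_bed(promoters: Sequence[Promoter], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "chrom": [p.chrom for p in promoters],
            "start": [p.start for p in promoters],
            "end": [p.end for p in promoters],
            "gene_id": [p.gene_id for p in promoters],
            "score": 0,
            "strand": [p.strand for p in promoters],
        }
    )
    df.to_csv(path, sep="\t", header=False, index=False)


@dataclass(frozen=True)
class Comparison:
    """A two-group contrast; effect sign convention is mean(a) - mean(b),
    so "FFC vs SD" means group_a=FFC, group_b=SD."""

    name: str
    group_a: str
    group_b: str

    def __post_init__(self) -> None:
        if self.group_a == self.group_b:
            raise ValueError("comparison groups must differ")

    @classmethod
    def versus(cls, group_a: str, group_b: str) -> "Comparison":
        return cls(name=f"{group_a} vs {group_b}", group_a=group_a, group_b=group_b)

    def swapped(self) -> "Comparison":
        return Comparison(
            name=f"{self.group_b} vs {self.group_a}",
            group_a=self.group_b,
            group_b=self.group_a,
        )


@dataclass
class PhenotypeTable:
    """Sample-to-group assignment plus numeric phenotype measurements.

    ``data`` is indexed by sample_id and carries a ``group`` column plus
    numeric phenotype columns (missing values allowed).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if "group" not in self.data.columns:
            raise ValueError("phenotype table requires a 'group' column")
        if self.data.index.duplicated().any():
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValueError(f"duplicate sample id {dup!r}")

    @property
    def samples(self) -> list[str]:
        return list(self.data.index)

    @property
    def groups(self) -> pd.Series:
        return self.data["group"]

    def group_census(self) -> dict[str, int]:
        return self.data["group"].value_counts().to_dict()

    def phenotype_columns(self) -> list[str]:
        return [c for c in self.data.columns if c != "group"]


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    """Read a phenotype TSV with header; requires sample_id and group columns.

    Non-numeric phenotype cells become missing (with a warning); unknown
    phenotype columns are preserved as numeric.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "group"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"{path}: duplicate sample id {dup!r}")
    df = df.set_index("sample_id")
    for col in df.columns:
        if col == "group":
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        newly_missing = coerced.isna() & df[col].notna() & (df[col].str.strip() != "")
        if newly_missing.any():
            warnings.warn(
                f"{path}: {int(newly_missing.sum())} non-numeric value(s) in "
                f"column {col!r} treated as missing"
            )
        df[col] = coerced
    return PhenotypeTable(data=df)


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    """Write a result TSV with floats at 6 significant digits and NA for missing."""
    df.to_csv(path, sep="\t", index=index, float_format="%.6g", na_rep="NA")
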