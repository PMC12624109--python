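"""Tabular I/O for the pipeline: sample×feature matrices, annotation tables
and the bundled seven-axis summary fixture.

All files are UTF-8, tab-delimited, with "NA" for missing values.  Matrices
carry sample IDs in the first column and feature IDs in the header row.
Positions in the native annotation table are 1-based and fully closed;
BED-like input (0-based, half-open) is converted on read.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "MatrixValidationError",
    "AnnotationRecord",
    "SummaryAxisRow",
    "read_matrix",
    "write_matrix",
    "read_annotation",
    "read_bed_annotation",
    "write_annotation",
    "load_reported_axes",
]

_NA = "NA"
_ALLELE_RE = re.compile(r"^[ACGT]+>[ACGT]+$")
_MATRIX_KINDS = ("genotype", "methylation", "expression")


class MatrixValidationError(ValueError):
    """A matrix file failed validation; the message names the offending cell."""


@dataclass(frozen=True)
class AnnotationRecord:
    """One genomic feature (CpG probe or SNP).

    ``position`` is 1-based.  ``alleles`` is a ``ref>variant`` string for
    SNPs (the second allele is the counted/dosage allele); None for CpGs.
    """

    feature_id: str
    chromosome: str
    position: int
    gene_symbol: str | None = None
    alleles: str | None = None

    def __post_init__(self):
        if self.position <= 0:
            raise ValueError(f"{self.feature_id}: position must be positive, got {self.position}")
        if self.alleles is not None and not _ALLELE_RE.match(self.alleles):
            raise ValueError(f"{self.feature_id}: malformed allele string {self.alleles!r}")

    @property
    def variant_allele(self) -> str | None:
        return None if self.alleles is None else self.alleles.split(">")[1]


@dataclass(frozen=True)
class SummaryAxisRow:
    """One SNP–CpG–gene axis from the bundled published summary.

    Combines the meQTL evidence (effect-direction sign and p in lung tissue
    and in blood), the tumor-vs-normal methylation and expression calls, the
    methylation–expression correlation ``r``, and the case-control genotype
    counts with the age-adjusted additive-model odds ratio.
    """

    cpg_id: str
    snp_id: str
    gene_symbol: str
    location: str
    alleles: str
    beta_sign_tissue: str
    meqtl_p_tissue: float
    beta_sign_blood: str
    meqtl_p_blood: float
    tumor_meth_level: str
    tumor_expr_level: str
    r: float
    genotype_counts_cases: tuple[int, int, int]
    genotype_counts_controls: tuple[int, int, int]
    maf_cases: float
    maf_controls: float
    or_value: float
    ci_low: float
    ci_high: float
    p_value: float
    # the CpG-island coordinate reported separately from the table locus for
    # cg09596674; stored unreconciled
    cpg_position_alt: str | None = field(default=None, compare=False)

    def __post_init__(self):
        for sign in (self.beta_sign_tissue, self.beta_sign_blood):
            if sign not in {"+", "-"}:
                raise ValueError(f"{self.snp_id}: beta sign must be '+' or '-', got {sign!r}")
        for level in (self.tumor_meth_level, self.tumor_expr_level):
            if level not in {"High", "Low"}:
                raise ValueError(f"{self.snp_id}: level must be High/Low, got {level!r}")
        for p in (self.meqtl_p_tissue, self.meqtl_p_blood, self.p_value):
            if not (0.0 < p <= 1.0):
                raise ValueError(f"{self.snp_id}: p-value out of (0,1]: {p}")
        if abs(self.r) > 1.0:
            raise ValueError(f"{self.snp_id}: |r| > 1: {self.r}")
        for counts in (self.genotype_counts_cases, self.genotype_counts_controls):
            if len(counts) != 3 or any(c < 0 or c != int(c) for c in counts):
                raise ValueError(f"{self.snp_id}: genotype counts must be 3 nonnegative ints")
        if not (self.ci_low <= self.or_value <= self.ci_high):
            raise ValueError(f"{self.snp_id}: CI does not bracket OR")


def _check_rectangular(path: Path) -> None:
    """Reject ragged files before handing them to pandas."""
    widths = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            widths.add(len(line.rstrip("\n").split("\t")))
            if len(widths) > 1:
                raise MatrixValidationError(f"{path}: ragged row at line {lineno}")


def read_matrix(path, kind: str) -> pd.DataFrame:
    """Read and validate a sample×feature matrix.

    ``kind`` selects the value contract: ``genotype`` entries must be
    integral dosages in {0,1,2}; ``methylation`` entries must lie strictly in
    (0,1); ``expression`` entries must be nonnegative.
    """
    if kind not in _MATRIX_KINDS:
        raise ValueError(f"kind must be one of {_MATRIX_KINDS}, got {kind!r}")
    path = Path(path)
    _check_rectangular(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    seen: set[str] = set()
    for name in header:  # before pandas mangles duplicates to "x.1"
        if name in seen:
            raise MatrixValidationError(f"{path}: duplicate feature ID {name!r}")
        seen.add(name)
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[_NA],
                     keep_default_na=False, float_precision="round_trip")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise MatrixValidationError(f"{path}: duplicate sample ID {dup!r}")
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad][0]
            raise MatrixValidationError(
                f"{path}: non-numeric cell at sample {row!r}, feature {col!r}: {df.loc[row, col]!r}"
            )
        df[col] = vals
    if df.isna().any().any():
        col = df.columns[df.isna().any()][0]
        row = df.index[df[col].isna()][0]
        raise MatrixValidationError(f"{path}: missing value at sample {row!r}, feature {col!r}")
    arr = df.to_numpy(dtype=float)
    if kind == "genotype":
        if not np.all(np.isin(arr, (0.0, 1.0, 2.0))):
            i, j = np.argwhere(~np.isin(arr, (0.0, 1.0, 2.0)))[0]
            raise MatrixValidationError(
                f"{path}: genotype dosage out of {{0,1,2}} at sample "
                f"{df.index[i]!r}, SNP {df.columns[j]!r}: {arr[i, j]}"
            )
        df = df.astype(np.int64)
    elif kind == "methylation":
        if not np.all((arr > 0.0) & (arr < 1.0)):
            i, j = np.argwhere(~((arr > 0.0) & (arr < 1.0)))[0]
            raise MatrixValidationError(
                f"{path}: beta value outside (0,1) at sample "
                f"{df.index[i]!r}, CpG {df.columns[j]!r}: {arr[i, j]}"
            )
    else:  # expression
        if not np.all(arr >= 0.0):
            i, j = np.argwhere(arr < 0.0)[0]
            raise MatrixValidationError(
                f"{path}: negative expression at sample "
                f"{df.index[i]!r}, gene {df.columns[j]!r}: {arr[i, j]}"
            )
    df.index.name = "sample_id"
    return df


def write_matrix(df: pd.DataFrame, path) -> None:
    """Write a matrix so that :func:`read_matrix` recovers it exactly."""
    df.to_csv(path, sep="\t", index_label="sample_id", na_rep=_NA)


def read_annotation(path) -> list[AnnotationRecord]:
    """Read the native 1-based annotation table.

    Columns: feature_id, chromosome, position, gene_symbol, alleles (the
    last two optional/NA).
    """
    path = Path(path)
    _check_rectangular(path)
    df = pd.read_csv(path, sep="\t", na_values=[_NA], keep_default_na=False)
    records = []
    for row in df.itertuples(index=False):
        records.append(
            AnnotationRecord(
                feature_id=str(row.feature_id),
                chromosome=str(row.chromosome),
                position=int(row.position),
                gene_symbol=None if pd.isna(getattr(row, "gene_symbol", None)) else str(row.gene_symbol),
                alleles=None if pd.isna(getattr(row, "alleles", None)) else str(row.alleles),
            )
        )
    return records


def read_bed_annotation(path) -> list[AnnotationRecord]:
    """Read a 4-column BED-like table (chrom, start, end, id; 0-based
    half-open) and convert to 1-based positions (position = start + 1)."""
    path = Path(path)
    _check_rectangular(path)
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end", "feature_id"])
    return [
        AnnotationRecord(feature_id=str(r.feature_id), chromosome=str(r.chrom), position=int(r.start) + 1)
        for r in df.itertuples(index=False)
    ]


def write_annotation(records: list[AnnotationRecord], path) -> None:
    rows = [
        {
            "feature_id": r.feature_id,
            "chromosome": r.chromosome,
            "position": r.position,
            "gene_symbol": r.gene_symbol if r.gene_symbol is not None else _NA,
            "alleles": r.alleles if r.alleles is not None else _NA,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def load_reported_axes() -> list[SummaryAxisRow]:
    """Load the bundled seven SNP–CpG–gene axes from the non-smoking LUAD
    meQTL susceptibility study (effect directions, tumor methylation and
    expression calls, correlation, genotype counts, age-adjusted ORs).
    """
    with resources.files("meqaxis.data").joinpath("luad_meqtl_axes.tsv").open("r", encoding="utf-8") as fh:
        df = pd.read_csv(fh, sep="\t", na_values=[_NA], keep_default_na=False)
    rows = []
    for r in df.itertuples(index=False):
        rows.append(
            SummaryAxisRow(
                cpg_id=r.cpg_id,
                snp_id=r.snp_id,
                gene_symbol=r.gene_symbol,
                location=r.location,
                alleles=r.alleles,
                beta_sign_tissue=r.beta_sign_tissue,
                meqtl_p_tissue=float(r.meqtl_p_tissue),
                beta_sign_blood=r.beta_sign_blood,
                meqtl_p_blood=float(r.meqtl_p_blood),
                tumor_meth_level=r.tumor_meth_level,
                tumor_expr_level=r.tumor_expr_level,
                r=float(r.r),
                genotype_counts_cases=(int(r.cases_n0), int(r.cases_n1), int(r.cases_n2)),
                genotype_counts_controls=(int(r.controls_n0), int(r.controls_n1), int(r.controls_n2)),
                maf_cases=float(r.maf_cases),
                maf_controls=float(r.maf_controls),
                or_value=float(r.or_value),
                ci_low=float(r.ci_low),
                ci_high=float(r.ci_high),
                p_value=float(r.p_value),
                cpg_position_alt=None if pd.isna(r.cpg_position_alt) else str(r.cpg_position_alt),
            )
        )
    if len(rows) != 7:
        raise RuntimeError(f"expected 7 bundled axes, found {len(rows)}")
    return rows
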