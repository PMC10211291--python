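"""Readers and writers for every on-disk format the pipeline touches.

Dialects
--------
* Matrices and tables: tab-separated, UTF-8, ``.`` decimal, header row.
* Sample sheets: comma-separated.
* CpG positions: BED3+name (0-based half-open, name = CpG id).
* Catalog sets: GMT (set name TAB description TAB ids...).
* Genotypes: TSV dosage matrix (snp_id, chrom, pos, one column per
  sample) or VCF v4.x with GT fields. VCF positions (1-based) are
  converted to 0-based internally.

Every reader rejects files that violate its dialect with a message
naming the offending record; every writer produces files its reader
accepts (round-trip identity to 10 decimal places for matrices).
"""

from __future__ import annotations

import csv
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from methylcell.methio.core import (
    BetaMatrix,
    CpGAnnotation,
    GeneAnnotation,
    GenotypeMatrix,
    SampleSheet,
    ValidationError,
)

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"


# ---------------------------------------------------------------------------
# beta matrices
# ---------------------------------------------------------------------------

def read_beta(path) -> BetaMatrix:
    """Read a CpG x sample beta matrix from TSV.

    First column must be named ``cpg_id``. Ragged rows and values
    outside [0, 1] are rejected with the offending line / cell named.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ValidationError(f"{path}: empty file, expected a header row")
        if not header or header[0] != "cpg_id":
            raise ValidationError(
                f"{path}: first column must be 'cpg_id', got {header[:1]!r}"
            )
        samples = header[1:]
        cpgs: list[str] = []
        rows: list[list[float]] = []
        for lineno, row in enumerate(reader, start=2):
            if len(row) != len(header):
                raise ValidationError(
                    f"{path}: ragged row at line {lineno} "
                    f"({len(row)} fields, expected {len(header)})"
                )
            cpgs.append(row[0])
            try:
                values = [float(v) for v in row[1:]]
            except ValueError as exc:
                raise ValidationError(
                    f"{path}: non-numeric beta at line {lineno}: {exc}"
                )
            rows.append(values)
    df = pd.DataFrame(rows, index=pd.Index(cpgs, name="cpg_id"), columns=samples)
    for cpg, sample in zip(*np.where((df.values < 0) | (df.values > 1))):
        raise ValidationError(
            f"{path}: beta out of range [0, 1] at CpG {df.index[cpg]!r}, "
            f"sample {df.columns[sample]!r}"
        )
    return BetaMatrix(df)


def write_beta(beta: BetaMatrix, path) -> None:
    beta.df.to_csv(path, sep="\t", float_format=_FLOAT_FMT, index_label="cpg_id")


# ---------------------------------------------------------------------------
# sample sheets
# ---------------------------------------------------------------------------

def read_sample_sheet(path) -> SampleSheet:
    df = pd.read_csv(path, dtype={"sample_id": str, "subject_id": str})
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    sheet.df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# BED / gene annotation
# ---------------------------------------------------------------------------

def read_bed(path) -> CpGAnnotation:
    """Read CpG positions from BED3+name (chrom, start, end, cpg_id)."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "cpg_id"],
        dtype={"chrom": str, "cpg_id": str},
    )
    if (df["end"] - df["start"] != 1).any():
        bad = df.loc[df["end"] - df["start"] != 1, "cpg_id"].tolist()
        raise ValidationError(f"CpG BED intervals must have width 1: {bad[:5]}")
    return CpGAnnotation(df.rename(columns={"start": "pos"})[["cpg_id", "chrom", "pos"]])


def write_bed(annot: CpGAnnotation, path) -> None:
    out = annot.df.copy()
    out["start"] = out["pos"]
    out["end"] = out["pos"] + 1
    out[["chrom", "start", "end", "cpg_id"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_gene_annotation(path) -> GeneAnnotation:
    return GeneAnnotation(pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str}))


def write_gene_annotation(annot: GeneAnnotation, path) -> None:
    annot.df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def read_genotypes(path, format: str = "tsv") -> GenotypeMatrix:
    """Read a dosage matrix from TSV or VCF.

    TSV columns: snp_id, chrom, pos, then one column per sample.
    VCF: GT fields are summed to dosages; multi-allelic records are
    skipped with a warning; missing genotypes are an error.
    """
    if format == "tsv":
        return _read_genotypes_tsv(path)
    if format == "vcf":
        return _read_genotypes_vcf(path)
    raise ValidationError(f"unknown genotype format {format!r}")


def _read_genotypes_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "chrom": str})
    for col in ("snp_id", "chrom", "pos"):
        if col not in df.columns:
            raise ValidationError(f"{path}: genotype TSV missing column {col!r}")
    snps = df[["snp_id", "chrom", "pos"]]
    dosages = df.drop(columns=["chrom", "pos"]).set_index("snp_id")
    return GenotypeMatrix(dosages, snps)


def _read_genotypes_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF  # heavy import, deferred

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ids, chroms, poss, rows = [], [], [], []
    n_multiallelic = 0
    for variant in vcf:
        if len(variant.ALT) != 1:
            n_multiallelic += 1
            warnings.warn(
                f"skipping multi-allelic record {variant.ID or variant.POS} "
                f"({len(variant.ALT)} ALT alleles)"
            )
            continue
        dosage = []
        for sample, gt in zip(samples, variant.genotypes):
            alleles = gt[:-1]
            if any(a < 0 for a in alleles):
                raise ValidationError(
                    f"missing genotype at SNP {variant.ID or variant.POS} for "
                    f"sample {sample}; no imputation is performed"
                )
            dosage.append(sum(1 for a in alleles if a > 0))
        ids.append(variant.ID or f"{variant.CHROM}:{variant.POS}")
        chroms.append(variant.CHROM)
        poss.append(variant.POS - 1)  # VCF is 1-based; internal is 0-based
        rows.append(dosage)
    if n_multiallelic:
        logger.info("skipped %d multi-allelic VCF records", n_multiallelic)
    dosages = pd.DataFrame(rows, index=pd.Index(ids, name="snp_id"), columns=samples)
    snps = pd.DataFrame({"snp_id": ids, "chrom": chroms, "pos": poss})
    return GenotypeMatrix(dosages, snps)


def write_genotypes(geno: GenotypeMatrix, path) -> None:
    out = geno.snps.merge(
        geno.dosages.reset_index(), on="snp_id", validate="one_to_one"
    )
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GMT catalog sets
# ---------------------------------------------------------------------------

def read_gmt(path) -> dict[str, dict]:
    """Read GMT: one set per line, ``name TAB description TAB id...``."""
    sets: dict[str, dict] = {}
    with Path(path).open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"{path}: GMT line {lineno} has {len(fields)} fields, need >= 3"
                )
            name, description = fields[0], fields[1]
            if name in sets:
                raise ValidationError(f"{path}: duplicate set name {name!r}")
            ids = fields[2:]
            if len(set(ids)) != len(ids):
                raise ValidationError(
                    f"{path}: duplicate ids within set {name!r} (line {lineno})"
                )
            sets[name] = {"description": description, "ids": list(ids)}
    return sets


def write_gmt(sets: dict[str, dict], path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for name, entry in sets.items():
            fh.write("\t".join([name, entry["description"], *entry["ids"]]) + "\n")


# ---------------------------------------------------------------------------
# QTL / GWAS summary tables
# ---------------------------------------------------------------------------

QTL_COLUMNS = ["study_id", "snp_id", "snp_chrom", "snp_pos", "target_id", "target_type", "p"]
GWAS_COLUMNS = ["snp_id", "chrom", "pos", "trait", "p", "n"]


def read_qtl_table(path) -> pd.DataFrame:
    """Read a QTL summary TSV.

    Columns: study_id, snp_id, snp_chrom, snp_pos, target_id,
    target_type {cpg,gene}, p. For eQTM tables the ``snp_id`` slot
    carries the source CpG id with its coordinates.
    """
    df = pd.read_csv(path, sep="\t", dtype={"study_id": str, "snp_id": str, "target_id": str})
    missing = [c for c in QTL_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: QTL table missing columns {missing}")
    if not set(df["target_type"].unique()) <= {"cpg", "gene"}:
        raise ValidationError(f"{path}: target_type must be 'cpg' or 'gene'")
    if ((df["p"] <= 0) | (df["p"] > 1)).any():
        bad = df.loc[(df["p"] <= 0) | (df["p"] > 1)].iloc[0]
        raise ValidationError(
            f"{path}: p value out of (0, 1] for {bad['snp_id']}->{bad['target_id']}"
        )
    return df[QTL_COLUMNS]


def write_qtl_table(df: pd.DataFrame, path) -> None:
    df[QTL_COLUMNS].to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_gwas(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "chrom": str, "trait": str})
    missing = [c for c in GWAS_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: GWAS table missing columns {missing}")
    return df[GWAS_COLUMNS]


def write_gwas(df: pd.DataFrame, path) -> None:
    df[GWAS_COLUMNS].to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
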