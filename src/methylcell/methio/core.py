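"""Core domain containers shared across the pipeline.

All genomic coordinates are 0-based, half-open. The only place 1-based
coordinates appear is the VCF reader, which converts at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

FRACTIONS = ("WB", "Bcell", "Gran", "Mono", "NK", "CD4T", "CD8T")
CELL_TYPES = ("Bcell", "Gran", "Mono", "NK", "CD4T", "CD8T")


class ValidationError(ValueError):
    """Raised when an input violates a declared contract."""


@dataclass
class BetaMatrix:
    """CpG x sample matrix of methylation proportions in [0, 1].

    ``df`` is indexed by CpG id (index name ``cpg_id``) with one column
    per sample id. Construction validates the invariants: unique ids,
    no missing values, all values in [0, 1].
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate CpG ids: {dups[:5]}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups[:5]}")
        values = df.to_numpy(dtype=float, copy=False)
        if values.size:
            if np.isnan(values).any():
                cpg, sample = self._first_offender(np.isnan(values))
                raise ValidationError(
                    f"missing beta value at CpG {cpg!r}, sample {sample!r}"
                )
            bad = (values < 0.0) | (values > 1.0)
            if bad.any():
                cpg, sample = self._first_offender(bad)
                raise ValidationError(
                    f"beta out of range [0, 1] at CpG {cpg!r}, sample {sample!r}"
                )
        self.df = df.astype(float)
        self.df.index.name = "cpg_id"

    def _first_offender(self, mask: np.ndarray) -> tuple[str, str]:
        i, j = np.argwhere(mask)[0]
        return str(self.df.index[i]), str(self.df.columns[j])

    @property
    def cpg_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.df.shape

    def subset_cpgs(self, cpg_ids) -> "BetaMatrix":
        return BetaMatrix(self.df.loc[list(cpg_ids)])

    def subset_samples(self, sample_ids) -> "BetaMatrix":
        return BetaMatrix(self.df[list(sample_ids)])


_SHEET_COLUMNS = [
    "sample_id",
    "subject_id",
    "fraction",
    "smoking",
    "age",
    "sex",
    "ancestry",
    "bmi",
]


@dataclass
class SampleSheet:
    """One row per assayed sample (subject x fraction).

    Columns: sample_id, subject_id, fraction, smoking {0,1}, age, sex
    {M,F}, ancestry (categorical), bmi. Missing covariates are refused,
    not imputed.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        missing = [c for c in _SHEET_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"sample sheet missing columns: {missing}")
        df = df[_SHEET_COLUMNS].copy()
        if df["sample_id"].duplicated().any():
            dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValidationError(f"duplicate sample ids: {dups[:5]}")
        bad_frac = set(df["fraction"]) - set(FRACTIONS)
        if bad_frac:
            raise ValidationError(f"unknown fraction labels: {sorted(bad_frac)}")
        if not set(df["smoking"].unique()) <= {0, 1}:
            raise ValidationError("smoking must be coded 0/1")
        if not set(df["sex"].unique()) <= {"M", "F"}:
            raise ValidationError("sex must be coded M/F")
        for col in ("age", "bmi"):
            if df[col].isna().any():
                subj = df.loc[df[col].isna(), "sample_id"].tolist()
                raise ValidationError(
                    f"missing {col} for samples {subj[:5]}; refusing to impute"
                )
        df["smoking"] = df["smoking"].astype(int)
        self.df = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df["sample_id"])

    def for_fraction(self, fraction: str) -> "SampleSheet":
        return SampleSheet(self.df[self.df["fraction"] == fraction])

    def for_samples(self, sample_ids) -> "SampleSheet":
        sub = self.df.set_index("sample_id").loc[list(sample_ids)].reset_index()
        return SampleSheet(sub)


@dataclass
class CpGAnnotation:
    """CpG genomic positions; ``df`` columns: cpg_id, chrom, pos (0-based)."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        for col in ("cpg_id", "chrom", "pos"):
            if col not in df.columns:
                raise ValidationError(f"CpG annotation missing column {col!r}")
        df = df[["cpg_id", "chrom", "pos"]].copy()
        if df["cpg_id"].duplicated().any():
            raise ValidationError("duplicate cpg_id in annotation")
        if df.duplicated(["chrom", "pos"]).any():
            raise ValidationError("duplicate (chrom, pos) in CpG annotation")
        df["pos"] = df["pos"].astype(int)
        self.df = df.reset_index(drop=True)

    def positions(self) -> pd.DataFrame:
        return self.df.set_index("cpg_id")


@dataclass
class GeneAnnotation:
    """Gene spans; columns gene_id, chrom, start, end (0-based half-open), strand."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        for col in ("gene_id", "chrom", "start", "end", "strand"):
            if col not in df.columns:
                raise ValidationError(f"gene annotation missing column {col!r}")
        df = df[["gene_id", "chrom", "start", "end", "strand"]].copy()
        df["start"] = df["start"].astype(int)
        df["end"] = df["end"].astype(int)
        if (df["start"] >= df["end"]).any():
            bad = df.loc[df["start"] >= df["end"], "gene_id"].tolist()
            raise ValidationError(f"gene span start >= end for {bad[:5]}")
        if not set(df["strand"].unique()) <= {"+", "-"}:
            raise ValidationError("strand must be '+' or '-'")
        self.df = df.reset_index(drop=True)


@dataclass
class GenotypeMatrix:
    """SNP x sample dosage matrix with SNP positions.

    ``dosages`` is indexed by snp_id with sample columns, values in
    {0, 1, 2}. ``snps`` has columns snp_id, chrom, pos (0-based).
    """

    dosages: pd.DataFrame
    snps: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        d = self.dosages
        if d.index.has_duplicates:
            raise ValidationError("duplicate SNP ids in genotype matrix")
        values = d.to_numpy(dtype=float)
        if values.size:
            if np.isnan(values).any():
                i, j = np.argwhere(np.isnan(values))[0]
                raise ValidationError(
                    f"missing genotype for SNP {d.index[i]!r}, sample "
                    f"{d.columns[j]!r}; no imputation is performed"
                )
            if not np.isin(values, (0.0, 1.0, 2.0)).all():
                i, j = np.argwhere(~np.isin(values, (0.0, 1.0, 2.0)))[0]
                raise ValidationError(
                    f"dosage not in {{0,1,2}} for SNP {d.index[i]!r}"
                )
        self.dosages = d.astype(int)
        self.dosages.index.name = "snp_id"
        if self.snps is None:
            self.snps = pd.DataFrame(
                {"snp_id": list(d.index), "chrom": "chr1", "pos": range(len(d))}
            )
        self.snps = self.snps[["snp_id", "chrom", "pos"]].reset_index(drop=True)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.dosages.index)

    def dosage(self, snp_id: str) -> np.ndarray:
        return self.dosages.loc[snp_id].to_numpy(dtype=float)
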