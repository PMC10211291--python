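"""Multi-omics integration: mQTL proxies, LD expansion to GWAS, cis
eQTM/eQTL evidence, and the per-CpG evidence tally.

All thresholds are strict inequalities exactly as configured; boundary
values are excluded. "Replicated" means the same (snp, cpg) pair passes
the p threshold in two or more distinct studies; effect-direction
harmonization is not required. LD is the squared Pearson correlation of
dosage vectors (composite LD), as computed by VCFtools on genotypes.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from methylcell.methio.core import (
    CpGAnnotation,
    GeneAnnotation,
    GenotypeMatrix,
    ValidationError,
)

logger = logging.getLogger(__name__)

LINK_COLUMNS = ["cpg_id", "proxy_snp", "gwas_snp", "r2", "trait", "gwas_p", "category"]


# ---------------------------------------------------------------------------
# mQTL proxying
# ---------------------------------------------------------------------------

def filter_mqtls(
    records: pd.DataFrame,
    cpg_annot: CpGAnnotation,
    p_max: float = 2e-11,
    dist_max: int = 10000,
    min_studies: int = 2,
) -> pd.DataFrame:
    """Keep (snp, cpg) pairs that pass p and cis-distance filters in at
    least ``min_studies`` distinct studies.

    Distance is absolute genomic distance on the same chromosome,
    strand-agnostic, strict ``< dist_max``; p is strict ``< p_max``.
    Records whose CpG is absent from the annotation are skipped and
    counted. Returns columns cpg_id, snp_id, n_studies, studies.
    """
    rec = records[records["target_type"] == "cpg"].copy()
    pos = cpg_annot.positions()
    known = rec["target_id"].isin(pos.index)
    n_skipped = int((~known).sum())
    if n_skipped:
        logger.info("filter_mqtls: %d records skipped (CpG not annotated)", n_skipped)
    rec = rec[known]
    rec = rec.join(pos, on="target_id")
    same_chrom = rec["snp_chrom"].astype(str) == rec["chrom"].astype(str)
    close = (rec["snp_pos"] - rec["pos"]).abs() < dist_max
    strong = rec["p"] < p_max
    passing = rec[same_chrom & close & strong]
    grouped = (
        passing.groupby(["target_id", "snp_id"])["study_id"]
        .agg(lambda s: sorted(set(s)))
        .reset_index()
    )
    grouped["n_studies"] = grouped["study_id"].map(len)
    kept = grouped[grouped["n_studies"] >= min_studies].copy()
    kept = kept.rename(columns={"target_id": "cpg_id", "study_id": "studies"})
    kept["studies"] = kept["studies"].map(",".join)
    kept = kept.sort_values(["cpg_id", "snp_id"], kind="mergesort").reset_index(drop=True)
    return kept[["cpg_id", "snp_id", "n_studies", "studies"]]


# ---------------------------------------------------------------------------
# LD
# ---------------------------------------------------------------------------

def ld_r2(genotypes: GenotypeMatrix, snp_a: str, snp_b: str) -> float:
    """Squared Pearson correlation of dosage vectors (composite LD)."""
    a = genotypes.dosage(snp_a)
    b = genotypes.dosage(snp_b)
    if a.std() == 0 or b.std() == 0:
        raise ValidationError(
            f"LD undefined: zero dosage variance for {snp_a if a.std() == 0 else snp_b}"
        )
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


# ---------------------------------------------------------------------------
# GWAS
# ---------------------------------------------------------------------------

def filter_gwas(hits: pd.DataFrame, p_max: float = 5e-8, n_min: int = 1000) -> pd.DataFrame:
    """Keep hits with p strictly below ``p_max`` and n strictly above
    ``n_min``; duplicate (snp, trait) rows collapse to the minimum p."""
    kept = hits[(hits["p"] < p_max) & (hits["n"] > n_min)].copy()
    kept = kept.sort_values("p", kind="mergesort")
    kept = kept.drop_duplicates(subset=["snp_id", "trait"], keep="first")
    return kept.sort_values(["snp_id", "trait"], kind="mergesort").reset_index(drop=True)


def link_gwas(
    proxies: pd.DataFrame,
    gwas_hits: pd.DataFrame,
    genotypes: GenotypeMatrix,
    r2_threshold: float = 0.95,
    trait_categories: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Link proxy mQTL SNPs to GWAS SNPs by identity or complete LD.

    A row is emitted when the proxy SNP *is* a GWAS SNP (r2 recorded as
    1) or its dosage r2 with a GWAS SNP strictly exceeds
    ``r2_threshold``. Pairs missing from the genotype matrix are
    skipped and counted. Trait categories come from an optional
    trait -> category map (default category "other").
    """
    trait_categories = trait_categories or {}
    genotyped = set(genotypes.snp_ids)
    n_skipped = 0
    rows = []
    gwas_rows = list(gwas_hits.itertuples(index=False))
    for proxy in proxies.itertuples(index=False):
        for hit in gwas_rows:
            if proxy.snp_id == hit.snp_id:
                r2 = 1.0
            else:
                if proxy.snp_id not in genotyped or hit.snp_id not in genotyped:
                    n_skipped += 1
                    continue
                r2 = ld_r2(genotypes, proxy.snp_id, hit.snp_id)
                if not r2 > r2_threshold:
                    continue
            rows.append(
                {
                    "cpg_id": proxy.cpg_id,
                    "proxy_snp": proxy.snp_id,
                    "gwas_snp": hit.snp_id,
                    "r2": r2,
                    "trait": hit.trait,
                    "gwas_p": hit.p,
                    "category": trait_categories.get(hit.trait, "other"),
                }
            )
    if n_skipped:
        logger.info("link_gwas: %d proxy/GWAS pairs skipped (not genotyped)", n_skipped)
    out = pd.DataFrame(rows, columns=LINK_COLUMNS)
    return out.sort_values(
        ["cpg_id", "proxy_snp", "gwas_snp", "trait"], kind="mergesort"
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# cis eQTM / eQTL
# ---------------------------------------------------------------------------

def _gene_windows(gene_annot: GeneAnnotation, pad: int = 10000) -> pd.DataFrame:
    win = gene_annot.df.copy()
    win["win_start"] = win["start"] - pad
    win["win_end"] = win["end"] + pad
    return win.set_index("gene_id")


def _cpg_in_window(cpg_pos, cpg_chrom, win) -> pd.Series:
    return (
        (cpg_chrom.astype(str) == win["chrom"].astype(str))
        & (cpg_pos >= win["win_start"])
        & (cpg_pos < win["win_end"])
    )


def filter_eqtm(
    records: pd.DataFrame,
    cpg_annot: CpGAnnotation,
    gene_annot: GeneAnnotation,
    p_max: float = 1e-5,
    pad: int = 10000,
) -> pd.DataFrame:
    """cis eQTM evidence: (cpg, gene) pairs with the CpG inside the
    gene's +-10 kb window (half-open) and p strictly below ``p_max``.

    ``records`` follow the QTL schema with the CpG id in the snp_id
    slot and the gene as target. The window is strand-agnostic.
    Returns cpg_id, gene_id, study_id, p.
    """
    rec = records[records["target_type"] == "gene"].copy()
    rec = rec.rename(columns={"snp_id": "cpg_id", "target_id": "gene_id"})
    pos = cpg_annot.positions()
    rec = rec[rec["cpg_id"].isin(pos.index) & rec["gene_id"].isin(set(gene_annot.df["gene_id"]))]
    rec = rec.join(pos, on="cpg_id")
    win = _gene_windows(gene_annot, pad)
    rec = rec.join(win[["chrom", "win_start", "win_end"]].add_prefix("gene_"), on="gene_id")
    in_cis = (
        (rec["chrom"].astype(str) == rec["gene_chrom"].astype(str))
        & (rec["pos"] >= rec["gene_win_start"])
        & (rec["pos"] < rec["gene_win_end"])
    )
    kept = rec[in_cis & (rec["p"] < p_max)]
    out = kept[["cpg_id", "gene_id", "study_id", "p"]]
    return out.sort_values(["cpg_id", "gene_id", "study_id"], kind="mergesort").reset_index(
        drop=True
    )


def filter_eqtl(
    records: pd.DataFrame,
    proxies: pd.DataFrame,
    cpg_annot: CpGAnnotation,
    gene_annot: GeneAnnotation,
    p_max: float = 1e-5,
    dist_max: int = 10000,
    pad: int = 10000,
) -> pd.DataFrame:
    """cis eQTL evidence anchored at mQTL proxy pairs.

    For each proxy (cpg, snp) pair, keeps eQTL records of that SNP on a
    gene when the SNP lies strictly within ``dist_max`` of the
    anchoring CpG and the CpG lies inside the gene's +-10 kb window and
    the eQTL p is strictly below ``p_max``. Evidence attaches to the
    CpG. Returns cpg_id, snp_id, gene_id, study_id, p.
    """
    rec = records[records["target_type"] == "gene"].copy()
    rec = rec.rename(columns={"target_id": "gene_id"})
    rec = rec[rec["gene_id"].isin(set(gene_annot.df["gene_id"]))]
    pairs = proxies[["cpg_id", "snp_id"]].drop_duplicates()
    merged = pairs.merge(rec, on="snp_id", how="inner")
    pos = cpg_annot.positions()
    merged = merged[merged["cpg_id"].isin(pos.index)]
    merged = merged.join(pos.add_prefix("cpg_"), on="cpg_id")
    win = _gene_windows(gene_annot, pad)
    merged = merged.join(
        win[["chrom", "win_start", "win_end"]].add_prefix("gene_"), on="gene_id"
    )
    snp_near = (merged["snp_pos"] - merged["cpg_pos"]).abs() < dist_max
    same_chrom = merged["snp_chrom"].astype(str) == merged["cpg_chrom"].astype(str)
    in_window = (
        (merged["cpg_chrom"].astype(str) == merged["gene_chrom"].astype(str))
        & (merged["cpg_pos"] >= merged["gene_win_start"])
        & (merged["cpg_pos"] < merged["gene_win_end"])
    )
    kept = merged[snp_near & same_chrom & in_window & (merged["p"] < p_max)]
    out = kept[["cpg_id", "snp_id", "gene_id", "study_id", "p"]]
    return out.sort_values(
        ["cpg_id", "snp_id", "gene_id", "study_id"], kind="mergesort"
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# evidence tally
# ---------------------------------------------------------------------------

def evidence_table(
    cpg_ids,
    mqtl_by_study: dict[str, pd.DataFrame] | None = None,
    eqtm_evidence: pd.DataFrame | None = None,
    eqtl_evidence: pd.DataFrame | None = None,
    links: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """One 0/1 flag column per provided omics dataset, plus the layer count.

    Datasets: each mQTL study (single-study pass of the p/cis filter),
    each eQTM study, each eQTL study, and GWAS linkage.
    """
    out = pd.DataFrame(index=pd.Index(sorted(cpg_ids), name="cpg_id"))
    if mqtl_by_study:
        for study, table in sorted(mqtl_by_study.items()):
            flagged = set(table["cpg_id"])
            out[f"mqtl_{study}"] = [int(c in flagged) for c in out.index]
    for prefix, ev in (("eqtm", eqtm_evidence), ("eqtl", eqtl_evidence)):
        if ev is not None and len(ev):
            for study in sorted(ev["study_id"].unique()):
                flagged = set(ev.loc[ev["study_id"] == study, "cpg_id"])
                out[f"{prefix}_{study}"] = [int(c in flagged) for c in out.index]
    if links is not None:
        flagged = set(links["cpg_id"])
        out["gwas_link"] = [int(c in flagged) for c in out.index]
    out["n_omics_layers"] = out.sum(axis=1)
    return out


def multi_omics_tally(evidence: pd.DataFrame, min_layers: int = 4) -> pd.DataFrame:
    """CpGs with at least ``min_layers`` supporting datasets, sorted by
    layer count (descending) then cpg_id."""
    n_datasets = len([c for c in evidence.columns if c != "n_omics_layers"])
    if min_layers > n_datasets:
        logger.warning(
            "min_layers=%d exceeds the %d provided datasets; result is empty",
            min_layers,
            n_datasets,
        )
    hits = evidence[evidence["n_omics_layers"] >= min_layers].reset_index()
    hits = hits.sort_values("cpg_id", kind="mergesort")
    hits = hits.sort_values("n_omics_layers", ascending=False, kind="mergesort")
    return hits.set_index("cpg_id")
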