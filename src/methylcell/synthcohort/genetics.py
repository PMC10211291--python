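"""Synthetic genotypes, QTL summary studies and toy catalogs.

Genotypes live in LD blocks: the two haplotype alleles of every SNP in
a block share a latent standard normal with per-SNP independent noise,
with the latent correlation calibrated by bisection so the dosage r2
hits the requested target in expectation. mQTL effects are added to the
whole-blood methylome linearly on the M scale; expression picks up
eQTL (dosage) and eQTM (methylation) terms. Per-"study" summary tables
are produced by regressing on independent subject subsamples, which is
what makes cross-study replication of true pairs likely and of null
pairs rare.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from methylcell.methio.core import (
    BetaMatrix,
    CpGAnnotation,
    GeneAnnotation,
    GenotypeMatrix,
    ValidationError,
)
from methylcell.synthcohort.methylomes import _from_m, _to_m
from methylcell.synthcohort.panel import _require_seed
from methylcell.synthcohort.types import TruthBundle

DEFAULT_TRAIT_CATEGORIES = {
    "FEV1/FVC ratio": "lung function",
    "FEV1": "lung function",
    "asthma": "disease risk",
    "Crohn's disease": "disease risk",
    "hypertension": "disease risk",
    "eosinophil count": "blood traits",
    "lymphocyte count": "blood traits",
    "educational attainment": "other",
    "height": "other",
}

_STUDY_SUBSAMPLE = 0.85


@dataclass
class GeneticsBundle:
    genotypes: GenotypeMatrix
    beta_wb: BetaMatrix  # whole-blood betas with mQTL effects injected
    expression: pd.DataFrame  # gene x subject
    gene_annot: GeneAnnotation
    mqtl_tables: dict[str, pd.DataFrame]
    eqtm_tables: dict[str, pd.DataFrame]
    eqtl_tables: dict[str, pd.DataFrame]
    gwas: pd.DataFrame
    catalog_associations: pd.DataFrame
    trait_categories: dict[str, str]
    truth: TruthBundle = field(default_factory=TruthBundle)


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def _calibrate_rho(target_r2: float, maf: float) -> float:
    """Latent Gaussian correlation giving allele-level r2 = target."""
    if target_r2 >= 1.0:
        return 1.0
    if target_r2 <= 0.0:
        return 0.0
    t = stats.norm.ppf(maf)
    denom = maf * (1.0 - maf)

    def dosage_r2(rho: float) -> float:
        p11 = stats.multivariate_normal(
            mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]]
        ).cdf([t, t])
        r = (p11 - maf * maf) / denom
        return r * r

    lo, hi = 0.0, 1.0 - 1e-9
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if dosage_r2(mid) < target_r2:
            lo = mid
        else:
            hi = mid
    return hi


def simulate_genotypes(
    subjects,
    cpg_annot: CpGAnnotation,
    n_blocks: int,
    snps_per_block: int,
    maf_range: tuple[float, float] = (0.1, 0.5),
    within_block_r2: float = 0.95,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    anchor_cpgs=None,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Block-correlated dosages anchored near CpG positions.

    Returns the genotype matrix and a block table (snp_id, block,
    anchor_cpg, maf). One MAF is drawn per block so that a target r2 of
    1 yields literally duplicated dosage columns. ``anchor_cpgs``
    optionally pins each block to a chosen CpG (default: evenly spaced
    over the annotation).
    """
    if rng is None:
        rng = _require_seed(seed)
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValidationError("maf_range must be contained in (0, 0.5]")
    subjects = list(subjects)
    n = len(subjects)
    annot = cpg_annot.df
    if anchor_cpgs is not None:
        anchor_cpgs = list(anchor_cpgs)
        if len(anchor_cpgs) != n_blocks:
            raise ValidationError("anchor_cpgs must provide one CpG per block")
        lookup = {c: i for i, c in enumerate(annot["cpg_id"])}
        missing = [c for c in anchor_cpgs if c not in lookup]
        if missing:
            raise ValidationError(f"anchor CpGs not in annotation: {missing[:5]}")
        anchor_idx = np.array([lookup[c] for c in anchor_cpgs])
    else:
        anchor_idx = np.linspace(0, len(annot) - 1, n_blocks).round().astype(int)
    ids, chroms, positions, rows, block_rows = [], [], [], [], []
    for b in range(n_blocks):
        anchor = annot.iloc[anchor_idx[b]]
        maf = float(rng.uniform(lo, hi))
        rho = _calibrate_rho(within_block_r2, maf)
        t = stats.norm.ppf(maf)
        z = rng.standard_normal((n, 2))  # shared block latent per haplotype
        offsets = rng.choice(np.arange(-8000, 8001), size=snps_per_block, replace=False)
        for s in range(snps_per_block):
            if rho >= 1.0:
                latent = z
            else:
                eps = rng.standard_normal((n, 2))
                latent = np.sqrt(rho) * z + np.sqrt(1.0 - rho) * eps
            dosage = (latent < t).sum(axis=1)
            snp_id = f"rs{b:03d}{s:02d}"
            ids.append(snp_id)
            chroms.append(str(anchor["chrom"]))
            positions.append(int(anchor["pos"]) + int(offsets[s]))
            rows.append(dosage)
            block_rows.append(
                {"snp_id": snp_id, "block": b, "anchor_cpg": anchor["cpg_id"], "maf": maf}
            )
    dosages = pd.DataFrame(rows, index=pd.Index(ids, name="snp_id"), columns=subjects)
    snps = pd.DataFrame({"snp_id": ids, "chrom": chroms, "pos": positions})
    return GenotypeMatrix(dosages, snps), pd.DataFrame(block_rows)


# ---------------------------------------------------------------------------
# effect injection
# ---------------------------------------------------------------------------

def inject_mqtl_effects(
    beta: BetaMatrix,
    genotypes: GenotypeMatrix,
    specs,
    subject_of_sample: dict[str, str],
) -> BetaMatrix:
    """Add ``slope * dosage`` on the M scale for each (snp, cpg, slope)."""
    if not specs:
        return beta
    known_snps = set(genotypes.snp_ids)
    values = _to_m(beta.df.to_numpy())
    cpg_index = {c: i for i, c in enumerate(beta.df.index)}
    subject_cols = [subject_of_sample[s] for s in beta.df.columns]
    for snp, cpg, slope in specs:
        if snp not in known_snps:
            raise ValidationError(f"mQTL effect references unknown SNP {snp!r}")
        if cpg not in cpg_index:
            raise ValidationError(f"mQTL effect references unknown CpG {cpg!r}")
        dosage = genotypes.dosages.loc[snp, subject_cols].to_numpy(dtype=float)
        values[cpg_index[cpg]] += slope * dosage
    return BetaMatrix(
        pd.DataFrame(_from_m(values), index=beta.df.index, columns=beta.df.columns)
    )


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------

def _simple_regression_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided p for the slope of y ~ x (equivalent to the Pearson t test)."""
    n = len(x)
    if n < 4 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return 1.0
    r = np.corrcoef(x, y)[0, 1]
    r = float(np.clip(r, -1.0 + 1e-15, 1.0 - 1e-15))
    tval = abs(r) * np.sqrt((n - 2) / (1.0 - r * r))
    return float(max(2.0 * stats.t.sf(tval, n - 2), 5e-324))


def _study_tables(
    pairs: pd.DataFrame,
    x_matrix: pd.DataFrame,
    y_matrix: pd.DataFrame,
    n_studies: int,
    study_prefix: str,
    target_type: str,
    rng: np.random.Generator,
) -> dict[str, pd.DataFrame]:
    """One summary table per study from independent subject subsamples.

    ``pairs`` columns: source_id, source_chrom, source_pos, target_id.
    ``x_matrix``/``y_matrix`` are feature x subject with shared columns.
    """
    subjects = list(x_matrix.columns)
    n_sub = max(4, int(round(_STUDY_SUBSAMPLE * len(subjects))))
    tables: dict[str, pd.DataFrame] = {}
    for s in range(n_studies):
        study_id = f"{study_prefix}{s + 1}"
        chosen = rng.choice(len(subjects), size=n_sub, replace=False)
        cols = [subjects[i] for i in chosen]
        X = x_matrix[cols]
        Y = y_matrix[cols]
        rows = []
        for pair in pairs.itertuples(index=False):
            p = _simple_regression_p(
                X.loc[pair.source_id].to_numpy(dtype=float),
                Y.loc[pair.target_id].to_numpy(dtype=float),
            )
            rows.append(
                {
                    "study_id": study_id,
                    "snp_id": pair.source_id,
                    "snp_chrom": pair.source_chrom,
                    "snp_pos": pair.source_pos,
                    "target_id": pair.target_id,
                    "target_type": target_type,
                    "p": p,
                }
            )
        tables[study_id] = pd.DataFrame(rows)
    return tables


def _cis_pairs(
    sources: pd.DataFrame, targets: pd.DataFrame, max_dist: int
) -> pd.DataFrame:
    """All same-chromosome (source, target) pairs within ``max_dist``.

    ``sources``: columns id, chrom, pos. ``targets``: id, chrom, start,
    end (point targets use start == pos, end == pos + 1).
    """
    rows = []
    for src in sources.itertuples(index=False):
        near = targets[
            (targets["chrom"].astype(str) == str(src.chrom))
            & (targets["start"] - max_dist < src.pos)
            & (src.pos < targets["end"] + max_dist)
        ]
        for tgt in near.itertuples(index=False):
            rows.append(
                {
                    "source_id": src.id,
                    "source_chrom": src.chrom,
                    "source_pos": src.pos,
                    "target_id": tgt.id,
                }
            )
    return pd.DataFrame(rows, columns=["source_id", "source_chrom", "source_pos", "target_id"])


# ---------------------------------------------------------------------------
# top-level generator
# ---------------------------------------------------------------------------

def simulate_genetics(
    cohort: pd.DataFrame,
    wb_beta: BetaMatrix,
    cpg_annot: CpGAnnotation,
    n_blocks: int = 8,
    snps_per_block: int = 4,
    maf_range: tuple[float, float] = (0.1, 0.5),
    within_block_r2: float = 0.95,
    mqtl_specs=None,
    eqtl_specs=None,
    eqtm_specs=None,
    n_auto_mqtl: int = 0,
    auto_slope: float = 1.5,
    n_mqtl_studies: int = 4,
    n_eqtm_studies: int = 2,
    n_eqtl_studies: int = 4,
    gwas_specs=None,
    n_catalog_sets: int = 30,
    catalog_set_size: int = 40,
    catalog_enriched_cpgs=(),
    anchor_cpgs=None,
    seed: int | None = None,
) -> GeneticsBundle:
    """Generate genotypes, expression, per-study QTL summaries and toy
    GWAS / EWAS catalogs, with truth recorded.

    ``mqtl_specs`` / ``eqtl_specs`` / ``eqtm_specs`` are explicit
    (source, target, slope) triples; unknown ids are an error.
    ``n_auto_mqtl`` instead wires the first k blocks: the block's first
    SNP drives its anchor CpG (slope ``auto_slope``), the block gene
    picks up matching eQTL/eQTM terms, and the GWAS catalog tags the
    block's last SNP (a complete-LD partner at high ``within_block_r2``).
    """
    rng = _require_seed(seed)
    subjects = list(cohort["subject_id"])
    subject_of_sample = {c: c.rsplit("-", 1)[0] if "-" in c else c for c in wb_beta.df.columns}
    if sorted(subject_of_sample.values()) != sorted(subjects):
        raise ValidationError("whole-blood beta columns do not match the cohort")

    genotypes, blocks = simulate_genotypes(
        subjects, cpg_annot, n_blocks, snps_per_block, maf_range, within_block_r2,
        rng=rng, anchor_cpgs=anchor_cpgs,
    )

    # auto-wiring of true effects
    mqtl_specs = list(mqtl_specs or [])
    eqtl_specs = list(eqtl_specs or [])
    eqtm_specs = list(eqtm_specs or [])
    gwas_specs = list(gwas_specs or [])
    traits = list(DEFAULT_TRAIT_CATEGORIES)
    if n_auto_mqtl > n_blocks:
        raise ValidationError("n_auto_mqtl cannot exceed n_blocks")
    gene_rows = []
    annot_pos = cpg_annot.positions()
    for b in range(n_blocks):
        block_snps = blocks.loc[blocks["block"] == b, "snp_id"].tolist()
        anchor_cpg = blocks.loc[blocks["block"] == b, "anchor_cpg"].iloc[0]
        pos = int(annot_pos.loc[anchor_cpg, "pos"])
        chrom = str(annot_pos.loc[anchor_cpg, "chrom"])
        gene_rows.append(
            {
                "gene_id": f"GENE{b:03d}",
                "chrom": chrom,
                "start": max(0, pos - 3000),
                "end": pos + 3000,
                "strand": "+" if b % 2 == 0 else "-",
            }
        )
        if b < n_auto_mqtl:
            mqtl_specs.append((block_snps[0], anchor_cpg, auto_slope))
            eqtl_specs.append((block_snps[0], f"GENE{b:03d}", 0.8))
            eqtm_specs.append((anchor_cpg, f"GENE{b:03d}", 0.5))
            gwas_specs.append(
                {
                    "snp_id": block_snps[-1],
                    "trait": traits[b % len(traits)],
                    "p": float(10.0 ** -rng.uniform(10, 30)),
                    "n": int(rng.integers(2000, 50000)),
                }
            )
    gene_annot = GeneAnnotation(pd.DataFrame(gene_rows))

    beta_wb = inject_mqtl_effects(wb_beta, genotypes, mqtl_specs, subject_of_sample)

    # expression: baseline + eQTL dosage terms + eQTM methylation terms
    gene_ids = list(gene_annot.df["gene_id"])
    expr = pd.DataFrame(
        rng.standard_normal((len(gene_ids), len(subjects))),
        index=pd.Index(gene_ids, name="gene_id"),
        columns=subjects,
    )
    m_wb = pd.DataFrame(
        _to_m(beta_wb.df.to_numpy()),
        index=beta_wb.df.index,
        columns=[subject_of_sample[c] for c in beta_wb.df.columns],
    )
    known_snps = set(genotypes.snp_ids)
    for snp, gene, slope in eqtl_specs:
        if snp not in known_snps:
            raise ValidationError(f"eQTL effect references unknown SNP {snp!r}")
        if gene not in set(gene_ids):
            raise ValidationError(f"eQTL effect references unknown gene {gene!r}")
        expr.loc[gene] += slope * genotypes.dosages.loc[snp, subjects].to_numpy(dtype=float)
    for cpg, gene, slope in eqtm_specs:
        if cpg not in set(beta_wb.df.index):
            raise ValidationError(f"eQTM effect references unknown CpG {cpg!r}")
        if gene not in set(gene_ids):
            raise ValidationError(f"eQTM effect references unknown gene {gene!r}")
        centered = m_wb.loc[cpg, subjects] - m_wb.loc[cpg, subjects].mean()
        expr.loc[gene] += slope * centered.to_numpy(dtype=float)

    # candidate cis pairs and per-study summary tables
    snp_sources = genotypes.snps.rename(columns={"snp_id": "id"})
    cpg_targets = cpg_annot.df.rename(columns={"cpg_id": "id"}).assign(
        start=lambda d: d["pos"], end=lambda d: d["pos"] + 1
    )[["id", "chrom", "start", "end"]]
    mqtl_pairs = _cis_pairs(snp_sources, cpg_targets, max_dist=10000)
    dosage_by_subject = genotypes.dosages[subjects]
    mqtl_tables = _study_tables(
        mqtl_pairs, dosage_by_subject, m_wb[subjects], n_mqtl_studies, "mqtl_study", "cpg", rng
    )

    gene_targets = gene_annot.df.rename(columns={"gene_id": "id"})[
        ["id", "chrom", "start", "end"]
    ]
    cpg_sources = cpg_annot.df.rename(columns={"cpg_id": "id"})
    eqtm_pairs = _cis_pairs(cpg_sources, gene_targets, max_dist=10000)
    eqtm_tables = _study_tables(
        eqtm_pairs, m_wb[subjects], expr, n_eqtm_studies, "eqtm_study", "gene", rng
    )
    eqtl_pairs = _cis_pairs(snp_sources, gene_targets, max_dist=20000)
    eqtl_tables = _study_tables(
        eqtl_pairs, dosage_by_subject, expr, n_eqtl_studies, "eqtl_study", "gene", rng
    )

    # toy GWAS catalog: requested hits plus filler rows failing the filters
    snp_pos = genotypes.snps.set_index("snp_id")
    gwas_rows = []
    for spec in gwas_specs:
        if spec["snp_id"] not in known_snps:
            raise ValidationError(f"GWAS spec references unknown SNP {spec['snp_id']!r}")
        gwas_rows.append(
            {
                "snp_id": spec["snp_id"],
                "chrom": str(snp_pos.loc[spec["snp_id"], "chrom"]),
                "pos": int(snp_pos.loc[spec["snp_id"], "pos"]),
                "trait": spec["trait"],
                "p": spec["p"],
                "n": spec["n"],
            }
        )
    for filler in range(2):  # sub-threshold rows, should never survive filters
        snp = genotypes.snp_ids[int(rng.integers(len(genotypes.snp_ids)))]
        gwas_rows.append(
            {
                "snp_id": snp,
                "chrom": str(snp_pos.loc[snp, "chrom"]),
                "pos": int(snp_pos.loc[snp, "pos"]),
                "trait": "underpowered trait",
                "p": float(10.0 ** -rng.uniform(2, 6)),
                "n": int(rng.integers(100, 900)),
            }
        )
    gwas = pd.DataFrame(gwas_rows)

    catalog = _make_catalog(
        universe=list(wb_beta.df.index),
        enriched_cpgs=list(catalog_enriched_cpgs),
        n_sets=n_catalog_sets,
        set_size=catalog_set_size,
        rng=rng,
    )

    truth = TruthBundle(
        true_mqtl_pairs=list(mqtl_specs),
        true_eqtl_pairs=list(eqtl_specs),
        true_eqtm_pairs=list(eqtm_specs),
    )
    truth.validate_ids(wb_beta.df.index, genotypes.snp_ids, gene_ids)
    return GeneticsBundle(
        genotypes=genotypes,
        beta_wb=beta_wb,
        expression=expr,
        gene_annot=gene_annot,
        mqtl_tables=mqtl_tables,
        eqtm_tables=eqtm_tables,
        eqtl_tables=eqtl_tables,
        gwas=gwas,
        catalog_associations=catalog,
        trait_categories=dict(DEFAULT_TRAIT_CATEGORIES),
        truth=truth,
    )


def _make_catalog(
    universe: list[str],
    enriched_cpgs: list[str],
    n_sets: int,
    set_size: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Association-level toy EWAS catalog.

    The first set concentrates the supplied "interesting" CpGs (e.g.
    the injected smoking effects); the rest are random draws from the
    universe. A sprinkle of rows fails the p / population-size filters.
    """
    traits = [f"trait_{i:02d}" for i in range(n_sets)]
    rows = []
    for i, trait in enumerate(traits):
        set_name = f"catalog_set_{i:02d}"
        if i == 0 and enriched_cpgs:
            core = [c for c in enriched_cpgs if c in set(universe)]
            n_fill = max(0, set_size - len(core))
            fill = rng.choice(
                [c for c in universe if c not in set(core)], size=n_fill, replace=False
            )
            ids = [*core, *fill]
        else:
            ids = list(rng.choice(universe, size=min(set_size, len(universe)), replace=False))
        for cpg in ids:
            array = "450k" if rng.random() < 0.7 else "EPIC"
            rows.append(
                {
                    "set_name": set_name,
                    "trait": trait if i else "smoking_related",
                    "cpg_id": cpg,
                    "p": float(10.0 ** -rng.uniform(8, 30)),
                    "array": array,
                    "n": int(rng.integers(150, 20000)),
                }
            )
        # two failing rows per set: weak p and tiny study
        for cpg in rng.choice(universe, size=2, replace=False):
            rows.append(
                {
                    "set_name": set_name,
                    "trait": trait if i else "smoking_related",
                    "cpg_id": cpg,
                    "p": float(10.0 ** -rng.uniform(3, 6)),
                    "array": "450k",
                    "n": 50,
                }
            )
    return pd.DataFrame(rows)
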