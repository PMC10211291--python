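"""Pipeline stages chained by the CLI.

Each stage reads its inputs from (and writes its outputs to) a single
run directory with stable filenames, so stages can be re-run
individually. All stage functions are plain Python and usable without
the CLI.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from methylcell import composite as composite_mod
from methylcell import deconv, enrich, ewas, integrate
from methylcell import synthcohort
from methylcell.methio import io as mio
from methylcell.methio.core import BetaMatrix, ValidationError
from methylcell.methio.qc import apply_qc

logger = logging.getLogger("methylcell")

FRACTION_ORDER = ["Bcell", "Gran", "Mono", "NK", "CD4T", "CD8T", "WB"]
CELL_TYPES = FRACTION_ORDER[:-1]
B_LINEAGE = ("NaiveB", "MemB")


def _outdir(out) -> Path:
    path = Path(out)
    path.mkdir(parents=True, exist_ok=True)
    return path


def _log_run(stage: str, config: dict, seed: int, out: Path) -> None:
    logger.info("stage=%s seed=%d out=%s", stage, seed, out)
    logger.info("resolved config: %s", json.dumps(config.get(stage, {}), sort_keys=True))
    with (out / f"config_{stage}.yaml").open("w") as fh:
        yaml.safe_dump({"stage": stage, "seed": seed, "config": config}, fh)


def _read_profiles(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="cpg_id")
    return df


# ---------------------------------------------------------------------------
# simulate
# ---------------------------------------------------------------------------

def stage_simulate(config: dict, seed: int, out) -> dict:
    out = _outdir(out)
    _log_run("simulate", config, seed, out)
    cohort_cfg = config["cohort"]
    panel_cfg = config["panel"]
    meth_cfg = config["methylomes"]
    gen_cfg = config["genetics"]

    specs = synthcohort.default_cell_type_specs()
    panel, annot = synthcohort.make_reference_panel(
        n_cpgs=panel_cfg["n_cpgs"],
        specs=specs,
        n_signature_per_type=panel_cfg["n_signature_per_type"],
        seed=seed,
    )
    type_panel = synthcohort.collapse_to_types(panel, specs)
    cohort = synthcohort.make_cohort(
        cohort_cfg["n_nonsmokers"],
        cohort_cfg["n_smokers"],
        cohort_cfg.get("covariates"),
        seed=seed + 1,
    )

    effects = _auto_effects(
        annot,
        panel,
        n_effects=meth_cfg["n_effects"],
        delta_min=meth_cfg["delta_min"],
        delta_max=meth_cfg["delta_max"],
        seed=seed + 2,
    )
    matrices, sheet, truth = synthcohort.simulate_methylomes(
        panel,
        cohort,
        specs,
        effects=tuple(effects),
        shift=meth_cfg["shift"],
        noise_sd=meth_cfg["noise_sd"],
        seed=seed + 3,
        dirichlet_conc=meth_cfg["dirichlet_conc"],
        subtype_jitter_sd=meth_cfg["subtype_jitter_sd"],
    )
    bundle = synthcohort.simulate_genetics(
        cohort,
        matrices["WB"],
        annot,
        n_blocks=gen_cfg["n_blocks"],
        snps_per_block=gen_cfg["snps_per_block"],
        maf_range=tuple(gen_cfg["maf_range"]),
        within_block_r2=gen_cfg["within_block_r2"],
        n_auto_mqtl=gen_cfg["n_mqtl_effects"],
        auto_slope=gen_cfg["mqtl_slope"],
        n_mqtl_studies=gen_cfg["n_mqtl_studies"],
        n_eqtm_studies=gen_cfg["n_eqtm_studies"],
        n_eqtl_studies=gen_cfg["n_eqtl_studies"],
        n_catalog_sets=gen_cfg["n_catalog_sets"],
        catalog_set_size=gen_cfg["catalog_set_size"],
        catalog_enriched_cpgs=[e.cpg_id for e in effects],
        # anchor LD blocks at injected effect CpGs so smCpGs carry mQTLs
        anchor_cpgs=(
            [e.cpg_id for e in effects[: gen_cfg["n_blocks"]]]
            if len(effects) >= gen_cfg["n_blocks"]
            else None
        ),
        seed=seed + 4,
    )
    matrices["WB"] = bundle.beta_wb  # mQTL effects live in whole blood

    # write everything
    panel.profiles.to_csv(out / "panel_leaves.tsv", sep="\t")
    type_panel.profiles.to_csv(out / "panel_types.tsv", sep="\t")
    mio.write_bed(annot, out / "cpgs.bed")
    mio.write_sample_sheet(sheet, out / "sample_sheet.csv")
    for fraction, beta in matrices.items():
        mio.write_beta(beta, out / f"beta_{fraction}.tsv")
    mio.write_genotypes(bundle.genotypes, out / "genotypes.tsv")
    mio.write_gene_annotation(bundle.gene_annot, out / "genes.tsv")
    bundle.expression.to_csv(out / "expression.tsv", sep="\t")
    for study, table in {**bundle.mqtl_tables, **bundle.eqtm_tables, **bundle.eqtl_tables}.items():
        mio.write_qtl_table(table, out / f"{study}.tsv")
    mio.write_gwas(bundle.gwas, out / "gwas.tsv")
    bundle.catalog_associations.to_csv(
        out / "ewas_catalog_associations.tsv", sep="\t", index=False
    )
    gmt = {
        name: {"description": group["trait"].iloc[0], "ids": list(dict.fromkeys(group["cpg_id"]))}
        for name, group in bundle.catalog_associations.groupby("set_name", sort=True)
    }
    mio.write_gmt(gmt, out / "ewas_catalog.gmt")
    truth.true_proportions.to_csv(out / "true_proportions.tsv", sep="\t")
    truth_json = {
        "effects": [
            {"cpg_id": e.cpg_id, "cell_type": e.cell_type, "delta": e.delta, "mechanism": e.mechanism}
            for e in effects
        ],
        "shift": meth_cfg["shift"],
        "mqtl_pairs": [list(p) for p in bundle.truth.true_mqtl_pairs],
        "eqtl_pairs": [list(p) for p in bundle.truth.true_eqtl_pairs],
        "eqtm_pairs": [list(p) for p in bundle.truth.true_eqtm_pairs],
        "signature_cpgs": panel.signature,
        "qtl_studies": {
            "mqtl": sorted(bundle.mqtl_tables),
            "eqtm": sorted(bundle.eqtm_tables),
            "eqtl": sorted(bundle.eqtl_tables),
        },
        "trait_categories": bundle.trait_categories,
    }
    with (out / "truth.json").open("w") as fh:
        json.dump(truth_json, fh, indent=1)
    return {"n_cpgs": panel_cfg["n_cpgs"], "n_subjects": len(cohort), "n_effects": len(effects)}


def _auto_effects(annot, panel, n_effects, delta_min, delta_max, seed):
    """Smoking effects of mixed cell-type origin over random CpGs.

    Roughly a third hit all cell types, a third the dominant myeloid
    types, and a third single lymphoid types, so whole blood sees a
    wide range of composite effect sizes.
    """
    rng = np.random.default_rng(seed)
    # avoid signature CpGs so deconvolution is undisturbed
    signature = set()
    if panel.signature:
        for ids in panel.signature.values():
            signature.update(ids)
    candidates = [c for c in panel.profiles.index if c not in signature]
    chosen = rng.choice(candidates, size=min(n_effects, len(candidates)), replace=False)
    origins = ["all", "Gran", "Mono", "Bcell", "CD4T", "CD8T", "NK"]
    weights = np.array([0.30, 0.25, 0.10, 0.15, 0.08, 0.06, 0.06])
    effects = []
    for cpg in chosen:
        origin = rng.choice(origins, p=weights / weights.sum())
        magnitude = rng.uniform(delta_min, delta_max)
        sign = -1.0 if rng.random() < 0.75 else 1.0  # smoking is mostly hypomethylating
        effects.append(synthcohort.EffectSpec(str(cpg), origin, sign * magnitude))
    return effects


# ---------------------------------------------------------------------------
# deconvolve
# ---------------------------------------------------------------------------

def stage_deconvolve(config: dict, seed: int, out) -> dict:
    out = _outdir(out)
    _log_run("deconvolve", config, seed, out)
    cfg = config["deconv"]
    leaf_panel = deconv.ReferencePanel(_read_profiles(out / "panel_leaves.tsv"))
    type_panel = deconv.ReferencePanel(_read_profiles(out / "panel_types.tsv"))
    sheet = mio.read_sample_sheet(out / "sample_sheet.csv")
    k = config["panel"]["n_signature_per_type"]
    type_sig = deconv.select_signature_cpgs(type_panel, k)
    leaf_sig = deconv.select_signature_cpgs(leaf_panel, k)

    props_parts = []
    for fraction in FRACTION_ORDER:
        beta = mio.read_beta(out / f"beta_{fraction}.tsv")
        props = deconv.estimate_proportions(beta, type_sig, constraint=cfg["constraint"])
        props_parts.append(props.df)
    proportions = pd.concat(props_parts)
    proportions.to_csv(out / "proportions.tsv", sep="\t")

    # 12-subtype estimation within the isolated B fraction
    beta_b = mio.read_beta(out / "beta_Bcell.tsv")
    sub_props = deconv.estimate_proportions(beta_b, leaf_sig, constraint=cfg["constraint"])
    sub_props.df.to_csv(out / "b_subtypes.tsv", sep="\t")
    b_sheet = sheet.for_fraction("Bcell")
    shift = deconv.shift_test_table(
        sub_props,
        b_sheet,
        subtypes=[s for s in B_LINEAGE if s in sub_props.cell_types],
        adjust=("age", "ancestry", "sex", "bmi"),
        renormalize=cfg["renormalize"],
        lineage=B_LINEAGE if cfg["renormalize"] else None,
    )
    shift.to_csv(out / "shift_test.tsv", sep="\t", index=False)
    naive = shift[shift["subtype"] == cfg["shift_subtype"]]
    return {
        "naive_diff": float(naive["diff"].iloc[0]) if len(naive) else None,
        "naive_p": float(naive["p"].iloc[0]) if len(naive) else None,
    }


# ---------------------------------------------------------------------------
# ewas
# ---------------------------------------------------------------------------

def stage_ewas(config: dict, seed: int, out) -> dict:
    out = _outdir(out)
    _log_run("ewas", config, seed, out)
    cfg = config["ewas"]
    sheet = mio.read_sample_sheet(out / "sample_sheet.csv")
    proportions = pd.read_csv(out / "proportions.tsv", sep="\t", index_col="sample_id")
    results: dict[str, pd.DataFrame] = {}
    counts = {}
    for fraction in FRACTION_ORDER:
        beta = mio.read_beta(out / f"beta_{fraction}.tsv")
        m = ewas.mvalue_transform(beta, eps=cfg["eps"])
        contamination = None
        own = None
        if cfg["adjust_contamination"]:
            contamination = deconv.ProportionTable(proportions.loc[beta.sample_ids])
            # one proportion column is dropped to avoid collinearity: the
            # fraction's own type, or the dominant type for whole blood
            own = fraction if fraction != "WB" else "Gran"
        table = ewas.fit_ewas(
            m,
            beta,
            sheet,
            contamination=contamination,
            own_cell_type=own,
            winsorize=cfg["winsorize"],
            winsorize_fraction=cfg["winsorize_fraction"],
        )
        table = ewas.multiple_testing(table)
        table.to_csv(out / f"ewas_{fraction}.tsv", sep="\t", index=False)
        results[fraction] = table
        counts[fraction] = {
            "bonferroni": int(table["bonferroni"].sum()),
            "fdr5": int((table["q"] < 0.05).sum()),
        }
    spec_table = ewas.specificity_table(
        {f: results[f] for f in CELL_TYPES},
        threshold=cfg["specificity_threshold"],
        ratio=cfg["specificity_ratio"],
    )
    spec_table.to_csv(out / "specificity.tsv", sep="\t", index=False)
    return counts


# ---------------------------------------------------------------------------
# composite
# ---------------------------------------------------------------------------

def stage_composite(config: dict, seed: int, out) -> dict:
    out = _outdir(out)
    _log_run("composite", config, seed, out)
    cfg = config["composite"]
    deltas = {}
    for fraction in FRACTION_ORDER:
        table = pd.read_csv(out / f"ewas_{fraction}.tsv", sep="\t", index_col="cpg_id")
        deltas[fraction] = table["delta_meth"]
    wb_table = pd.read_csv(out / "ewas_WB.tsv", sep="\t", index_col="cpg_id")
    delta_df = pd.DataFrame({t: deltas[t] for t in CELL_TYPES})
    weights = composite_mod.CompositeWeights(renormalize=cfg["renormalize"])
    table = composite_mod.composite_table(delta_df, deltas["WB"], weights)
    table.to_csv(out / "composite.tsv", sep="\t")
    wb_significant = wb_table.index[wb_table["bonferroni"]]
    summary = {}
    for subset in ("all", "myeloid", "lymphoid"):
        summary[subset] = composite_mod.compare_to_wholeblood(
            table[f"composite_{subset}"], deltas["WB"], wb_significant
        )
    with (out / "composite_summary.json").open("w") as fh:
        json.dump(summary, fh, indent=1)
    return summary["all"]


# ---------------------------------------------------------------------------
# integrate
# ---------------------------------------------------------------------------

def stage_integrate(config: dict, seed: int, out) -> dict:
    out = _outdir(out)
    _log_run("integrate", config, seed, out)
    cfg = config["integrate"]
    annot = mio.read_bed(out / "cpgs.bed")
    genes = mio.read_gene_annotation(out / "genes.tsv")
    genotypes = mio.read_genotypes(out / "genotypes.tsv")
    with (out / "truth.json").open() as fh:
        truth = json.load(fh)
    mqtl_records = {
        s: mio.read_qtl_table(out / f"{s}.tsv") for s in truth["qtl_studies"]["mqtl"]
    }
    eqtm_records = pd.concat(
        [mio.read_qtl_table(out / f"{s}.tsv") for s in truth["qtl_studies"]["eqtm"]]
    )
    eqtl_records = pd.concat(
        [mio.read_qtl_table(out / f"{s}.tsv") for s in truth["qtl_studies"]["eqtl"]]
    )
    gwas_raw = mio.read_gwas(out / "gwas.tsv")

    # smCpGs: union of Bonferroni hits over the six cell types
    smcpgs = set()
    for fraction in CELL_TYPES:
        table = pd.read_csv(out / f"ewas_{fraction}.tsv", sep="\t")
        smcpgs.update(table.loc[table["bonferroni"], "cpg_id"])

    all_mqtl = pd.concat(mqtl_records.values())
    all_mqtl = all_mqtl[all_mqtl["target_id"].isin(smcpgs)]
    proxies = integrate.filter_mqtls(
        all_mqtl,
        annot,
        p_max=cfg["mqtl_p_max"],
        dist_max=cfg["dist_max"],
        min_studies=cfg["min_studies"],
    )
    gwas_hits = integrate.filter_gwas(gwas_raw, cfg["gwas_p_max"], cfg["gwas_n_min"])
    links = integrate.link_gwas(
        proxies,
        gwas_hits,
        genotypes,
        r2_threshold=cfg["r2_threshold"],
        trait_categories=truth.get("trait_categories"),
    )
    links.to_csv(out / "links.tsv", sep="\t", index=False)

    eqtm_records = eqtm_records[eqtm_records["snp_id"].isin(smcpgs)]
    eqtm_ev = integrate.filter_eqtm(eqtm_records, annot, genes, p_max=cfg["eqtm_p_max"])
    eqtl_ev = integrate.filter_eqtl(
        eqtl_records, proxies, annot, genes,
        p_max=cfg["eqtl_p_max"], dist_max=cfg["dist_max"],
    )
    per_study_mqtl = {
        study: integrate.filter_mqtls(
            table[table["target_id"].isin(smcpgs)], annot,
            p_max=cfg["mqtl_p_max"], dist_max=cfg["dist_max"], min_studies=1,
        )
        for study, table in mqtl_records.items()
    }
    evidence = integrate.evidence_table(
        sorted(smcpgs), per_study_mqtl, eqtm_ev, eqtl_ev, links
    )
    evidence.to_csv(out / "evidence.tsv", sep="\t")
    prioritized = integrate.multi_omics_tally(evidence, min_layers=cfg["min_layers"])
    prioritized.to_csv(out / "prioritized.tsv", sep="\t")
    return {
        "n_smcpgs": len(smcpgs),
        "n_proxied_cpgs": int(proxies["cpg_id"].nunique()),
        "n_proxy_snps": int(proxies["snp_id"].nunique()),
        "n_linked_cpgs": int(links["cpg_id"].nunique()) if len(links) else 0,
        "n_prioritized": int(len(prioritized)),
    }


# ---------------------------------------------------------------------------
# enrich
# ---------------------------------------------------------------------------

def stage_enrich(config: dict, seed: int, out) -> dict:
    out = _outdir(out)
    _log_run("enrich", config, seed, out)
    cfg = config["enrich"]
    associations = pd.read_csv(out / "ewas_catalog_associations.tsv", sep="\t")
    sets = enrich.filter_catalog(associations, n_min=cfg["n_min"])

    tables = {
        f: pd.read_csv(out / f"ewas_{f}.tsv", sep="\t", index_col="cpg_id")
        for f in CELL_TYPES
    }
    min_p = pd.concat([t["p"] for t in tables.values()], axis=1).min(axis=1)
    scores = -np.log10(min_p)
    query = set()
    for table in tables.values():
        query.update(table.index[table["bonferroni"]])

    result = enrich.enrichment_analysis(
        query,
        sets,
        scores,
        weight_exponent=cfg["weight_exponent"],
        n_perm=cfg["n_perm"],
        seed=seed,
    )
    result.to_csv(out / "enrichment.tsv", sep="\t", index=False)
    if len(result):
        best = result.sort_values("fisher_p").iloc[0]
        return {"best_set": str(best["set"]), "best_fisher_p": float(best["fisher_p"])}
    return {"best_set": None, "best_fisher_p": None}


# ---------------------------------------------------------------------------
# run-all
# ---------------------------------------------------------------------------

STAGES = {
    "simulate": stage_simulate,
    "deconvolve": stage_deconvolve,
    "ewas": stage_ewas,
    "composite": stage_composite,
    "integrate": stage_integrate,
    "enrich": stage_enrich,
}


def run_all(config: dict, seed: int, out) -> dict:
    out = _outdir(out)
    summary = {}
    for name, stage in STAGES.items():
        summary[name] = stage(config, seed, out)
    with (out / "summary.json").open("w") as fh:
        json.dump(summary, fh, indent=1, default=str)
    return summary
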