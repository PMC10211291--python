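# methylcell

Cell-type-resolved smoking EWAS toolkit. The package implements, as a
reusable and fully tested pipeline:

* **synthcohort** — a synthetic cohort generator with complete ground
  truth: bimodal reference methylation panels (6 cell types / 12 leaf
  subtypes with signature CpGs), subject cohorts with covariates,
  per-fraction methylomes (isolated fractions with configurable purity
  plus whole blood as a Dirichlet mixture), a smoking-linked
  naive-to-memory B shift, LD-block genotypes with calibrated dosage
  r², per-"study" mQTL/eQTM/eQTL summary tables, and toy GWAS / EWAS
  catalogs.
* **methio** — readers/writers for every format (beta TSV, sample sheet
  CSV, BED, genotype TSV/VCF, GMT, QTL/GWAS TSV), detection-failure QC,
  YAML configuration, and the CLI.
* **deconv** — constrained-projection (NNLS with sum ≤ 1, optionally
  sum = 1) estimation of cell-type/subtype proportions and the
  subtype-shift regression test with covariate adjustment.
* **ewas** — M-value transform, per-CpG winsorization, Huber
  robust-regression EWAS (tuning 1.345, MAD scale) with covariate and
  contaminant-proportion adjustment, Bonferroni/BH multiple testing,
  cell-type-specificity calls (including the 10⁴ p-ratio rule) and
  directional concordance.
* **composite** — proportion-weighted reconstruction of whole-blood
  effects from cell-type effects, with myeloid/lymphoid sub-composites
  and correlation/slope comparison.
* **integrate** — mQTL proxy filtering (p < 2×10⁻¹¹, cis < 10 kb,
  replicated in ≥ 2 studies), complete-LD (dosage r² > 0.95) expansion
  to GWAS hits, cis eQTM/eQTL evidence, and the multi-omics tally.
* **enrich** — Fisher-exact (hypergeometric) overlap and pre-ranked
  permutation enrichment (ES/NES) against curated CpG sets.

## CLI

```sh
methylcell run-all --seed 1 --out runs/demo
# or stage by stage, sharing one run directory:
methylcell simulate   --seed 1 --out runs/demo
methylcell deconvolve --seed 1 --out runs/demo
methylcell ewas       --seed 1 --out runs/demo
methylcell composite  --seed 1 --out runs/demo
methylcell integrate  --seed 1 --out runs/demo
methylcell enrich     --seed 1 --out runs/demo
```

`--config FILE` overlays a YAML file on the built-in defaults (one
namespace per stage; see `methylcell.methio.config.default_config`).
Outputs use stable filenames (`beta_<fraction>.tsv`, `proportions.tsv`,
`shift_test.tsv`, `ewas_<fraction>.tsv`, `specificity.tsv`,
`composite.tsv`, `links.tsv`, `evidence.tsv`, `enrichment.tsv`,
`summary.json`). Exit code 0 on success, 2 on validation errors.

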