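"""Run configuration: one namespace per pipeline stage.

``default_config`` returns the full default tree; a YAML (or JSON —
YAML is a superset) file given via ``--config`` is deep-merged over it,
and individual CLI flags override both. Every run logs the resolved
config and seed.
"""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

_DEFAULTS: dict = {
    "cohort": {
        "n_nonsmokers": 74,
        "n_smokers": 67,
        "covariates": {
            "age_mean": 40.0,
            "age_sd": 12.0,
            "age_range": [18.0, 70.0],
            "sex_p_female": 0.5,
            "ancestry_probs": {"EUR": 0.6, "AFR": 0.3, "OTH": 0.1},
            "bmi_mean": 27.0,
            "bmi_sd": 5.0,
            "bmi_range": [16.0, 50.0],
        },
    },
    "panel": {
        "n_cpgs": 1200,
        "n_signature_per_type": 20,
    },
    "methylomes": {
        "noise_sd": 0.1,
        "shift": 0.072,
        "dirichlet_conc": 200.0,
        "subtype_jitter_sd": 0.06,
        "n_effects": 74,
        "delta_min": 0.02,
        "delta_max": 0.15,
    },
    "genetics": {
        "n_blocks": 8,
        "snps_per_block": 4,
        "maf_range": [0.1, 0.5],
        "within_block_r2": 0.98,
        "n_mqtl_studies": 4,
        "n_eqtm_studies": 2,
        "n_eqtl_studies": 4,
        "n_genes": 20,
        "n_mqtl_effects": 10,
        "mqtl_slope": 1.5,
        "n_catalog_sets": 30,
        "catalog_set_size": 40,
    },
    "deconv": {
        "constraint": "sum_le_1",
        "shift_subtype": "NaiveB",
        "renormalize": False,
    },
    "ewas": {
        "winsorize": False,
        "winsorize_fraction": 0.10,
        "eps": 1e-6,
        "specificity_threshold": "BF",
        "specificity_ratio": 1e4,
        "adjust_contamination": True,
    },
    "composite": {
        "renormalize": False,
    },
    "integrate": {
        "mqtl_p_max": 2e-11,
        "dist_max": 10000,
        "min_studies": 2,
        "gwas_p_max": 5e-8,
        "gwas_n_min": 1000,
        "r2_threshold": 0.95,
        "eqtm_p_max": 1e-5,
        "eqtl_p_max": 1e-5,
        "min_layers": 4,
    },
    "enrich": {
        "n_min": 100,
        "n_perm": 200,
        "weight_exponent": 1.0,
    },
}


def default_config() -> dict:
    return copy.deepcopy(_DEFAULTS)


def merge_config(base: dict, override: dict) -> dict:
    """Deep-merge ``override`` into a copy of ``base``."""
    merged = copy.deepcopy(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(merged.get(key), dict):
            merged[key] = merge_config(merged[key], value)
        else:
            merged[key] = copy.deepcopy(value)
    return merged


def load_config(path=None) -> dict:
    """Resolve the run configuration: defaults <- optional YAML/JSON file."""
    config = default_config()
    if path is not None:
        with Path(path).open(encoding="utf-8") as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ValueError(f"{path}: config must be a mapping")
        config = merge_config(config, user)
    return config
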