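"""Synthetic subject cohorts with configurable covariate distributions."""

from __future__ import annotations

import numpy as np
import pandas as pd

from methylcell.methio.core import ValidationError
from methylcell.synthcohort.panel import _require_seed

DEFAULT_COVARIATES = {
    "age_mean": 40.0,
    "age_sd": 12.0,
    "age_range": (18.0, 70.0),
    "sex_p_female": 0.5,
    "ancestry_probs": {"EUR": 0.6, "AFR": 0.3, "OTH": 0.1},
    "bmi_mean": 27.0,
    "bmi_sd": 5.0,
    "bmi_range": (16.0, 50.0),
}


def make_cohort(
    n_nonsmokers: int,
    n_smokers: int,
    covariate_config: dict | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """One subject row per person: subject_id, smoking {0,1}, age, sex
    {M,F}, ancestry, bmi. Age and BMI are truncated Gaussians; sex and
    ancestry categorical draws."""
    rng = _require_seed(seed)
    if n_nonsmokers < 2 or n_smokers < 2:
        raise ValidationError("need at least 2 subjects per smoking group")
    cfg = dict(DEFAULT_COVARIATES)
    if covariate_config:
        cfg.update(covariate_config)
    n = n_nonsmokers + n_smokers
    smoking = np.concatenate([np.zeros(n_nonsmokers, int), np.ones(n_smokers, int)])
    age = np.clip(
        rng.normal(cfg["age_mean"], cfg["age_sd"], n), *cfg["age_range"]
    )
    sex = np.where(rng.random(n) < cfg["sex_p_female"], "F", "M")
    ancestry_labels = sorted(cfg["ancestry_probs"])
    probs = np.array([cfg["ancestry_probs"][a] for a in ancestry_labels], dtype=float)
    ancestry = rng.choice(ancestry_labels, size=n, p=probs / probs.sum())
    bmi = np.clip(
        rng.normal(cfg["bmi_mean"], cfg["bmi_sd"], n), *cfg["bmi_range"]
    )
    return pd.DataFrame(
        {
            "subject_id": [f"S{i:04d}" for i in range(n)],
            "smoking": smoking,
            "age": np.round(age, 1),
            "sex": sex,
            "ancestry": ancestry,
            "bmi": np.round(bmi, 1),
        }
    )
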