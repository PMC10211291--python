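"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from methylcell import synthcohort
from methylcell.methio.core import BetaMatrix, SampleSheet


@pytest.fixture(scope="session")
def specs():
    return synthcohort.default_cell_type_specs()


@pytest.fixture(scope="session")
def pure_specs(specs):
    import dataclasses

    return tuple(dataclasses.replace(s, purity=1.0, subtypes=()) for s in specs)


@pytest.fixture(scope="session")
def small_panel(specs):
    """Leaf-level panel, 360 CpGs, 10 signature CpGs per leaf, seed 1."""
    panel, annot = synthcohort.make_reference_panel(
        n_cpgs=360, specs=specs, n_signature_per_type=10, seed=1
    )
    return panel, annot


@pytest.fixture(scope="session")
def small_cohort():
    return synthcohort.make_cohort(20, 20, seed=2)


def make_sheet(n: int, fraction: str = "Bcell", seed: int = 0, n_smokers=None) -> SampleSheet:
    rng = np.random.default_rng(seed)
    if n_smokers is None:
        n_smokers = n // 2
    smoking = np.array([0] * (n - n_smokers) + [1] * n_smokers)
    subjects = [f"S{i:03d}" for i in range(n)]
    return SampleSheet(
        pd.DataFrame(
            {
                "sample_id": [f"{s}-{fraction}" for s in subjects],
                "subject_id": subjects,
                "fraction": fraction,
                "smoking": smoking,
                "age": rng.uniform(20, 60, n).round(1),
                "sex": rng.choice(["M", "F"], n),
                "ancestry": rng.choice(["EUR", "AFR", "OTH"], n),
                "bmi": rng.uniform(20, 35, n).round(1),
            }
        )
    )


def random_beta(n_cpgs: int, sample_ids, seed: int = 0) -> BetaMatrix:
    rng = np.random.default_rng(seed)
    values = rng.uniform(0.05, 0.95, (n_cpgs, len(sample_ids)))
    return BetaMatrix(
        pd.DataFrame(
            values,
            index=pd.Index([f"cg{i:05d}" for i in range(n_cpgs)], name="cpg_id"),
            columns=list(sample_ids),
        )
    )
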