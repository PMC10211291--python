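"""Per-fraction methylome simulation.

For every subject the generator draws true whole-blood proportions from
a Dirichlet centered at the specs' mean proportions, composes each cell
type's pure profile from its subtype (leaf) profiles, injects direct
smoking effects into smokers' profiles before mixing, and assembles

* six isolated fractions: purity x own profile + (1 - purity) x a
  contaminant mix of the other cell types, and
* whole blood: the proportion-weighted sum of the pure profiles.

Measurement noise is Gaussian on the log2-ratio scale and transformed
back; betas are clamped to [1e-6, 1 - 1e-6]. The naive-to-memory shift
moves within-lineage mass between the two named subtypes for smokers;
``shift`` is expressed in fraction-of-isolated-fraction units (as
subtype tables report) and converted internally by the fraction purity.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from methylcell.deconv import ReferencePanel
from methylcell.methio.core import BetaMatrix, SampleSheet, ValidationError
from methylcell.synthcohort.panel import _require_seed
from methylcell.synthcohort.types import CellTypeSpec, EffectSpec, TruthBundle

BETA_EPS = 1e-6


def _to_m(beta: np.ndarray) -> np.ndarray:
    b = np.clip(beta, BETA_EPS, 1.0 - BETA_EPS)
    return np.log2(b / (1.0 - b))


def _from_m(m: np.ndarray) -> np.ndarray:
    x = np.exp2(m)
    return np.clip(x / (1.0 + x), BETA_EPS, 1.0 - BETA_EPS)


def simulate_methylomes(
    panel: ReferencePanel,
    cohort: pd.DataFrame,
    specs: tuple[CellTypeSpec, ...],
    effects: tuple[EffectSpec, ...] = (),
    shift: float = 0.0,
    noise_sd: float = 0.1,
    seed: int | None = None,
    dirichlet_conc: float = 200.0,
    subtype_jitter_sd: float = 0.0,
    shift_subtypes: tuple[str, str] = ("NaiveB", "MemB"),
) -> tuple[dict[str, BetaMatrix], SampleSheet, TruthBundle]:
    """Simulate the six isolated fractions plus whole blood.

    Returns ({fraction: BetaMatrix}, SampleSheet, TruthBundle). Sample
    ids are ``<subject>-<fraction>``. ``shift`` reduces smokers' share
    of ``shift_subtypes[0]`` (moving it to ``shift_subtypes[1]``) by
    that many fraction-level proportion points; ``subtype_jitter_sd``
    adds per-subject Gaussian jitter to the shifted subtype share.
    """
    rng = _require_seed(seed)
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    mean_props = np.array([s.mean_proportion for s in specs], dtype=float)
    if abs(mean_props.sum() - 1.0) > 0.01:
        raise ValidationError(
            f"mean proportions sum to {mean_props.sum():.4f}, expected 1 +- 0.01"
        )
    type_names = [s.name for s in specs]
    leaf_profiles = panel.profiles
    cpg_ids = list(leaf_profiles.index)
    cpg_index = {c: i for i, c in enumerate(cpg_ids)}
    for spec in specs:
        missing = [l for l in spec.leaf_labels if l not in leaf_profiles.columns]
        if missing:
            raise ValidationError(f"panel lacks leaf profiles {missing} for {spec.name}")
    for eff in effects:
        if eff.cpg_id not in cpg_index:
            raise ValidationError(f"effect references unknown CpG {eff.cpg_id!r}")
        if eff.cell_type != "all" and eff.cell_type not in type_names:
            raise ValidationError(f"effect references unknown cell type {eff.cell_type!r}")

    subjects = list(cohort["subject_id"])
    smoker = cohort["smoking"].to_numpy() == 1
    n_subj = len(subjects)
    n_cpgs = len(cpg_ids)

    # true whole-blood proportions (conc=inf pins them at the means)
    if np.isinf(dirichlet_conc):
        w = np.tile(mean_props / mean_props.sum(), (n_subj, 1))
    else:
        alpha = dirichlet_conc * mean_props / mean_props.sum()
        w = rng.dirichlet(alpha, size=n_subj)  # n_subj x n_types

    shift_type = None
    if shift != 0.0 or subtype_jitter_sd > 0.0:
        for spec in specs:
            if set(shift_subtypes) <= set(spec.leaf_labels):
                shift_type = spec.name
                break
        if shift_type is None and shift != 0.0:
            raise ValidationError(
                f"no spec contains both shift subtypes {shift_subtypes}"
            )

    # pure per-subject profiles per cell type (n_cpgs x n_subj each)
    pure: dict[str, np.ndarray] = {}
    subtype_share_record: dict[str, np.ndarray] = {}
    for spec in specs:
        shares = spec.lineage_shares()
        leaves = list(shares)
        share_matrix = np.tile(
            np.array([shares[l] for l in leaves]), (n_subj, 1)
        )  # n_subj x n_leaves
        if spec.name == shift_type:
            i_from = leaves.index(shift_subtypes[0])
            i_to = leaves.index(shift_subtypes[1])
            lineage_shift = shift / max(spec.purity, 1e-12)
            delta_share = np.where(smoker, lineage_shift, 0.0)
            if subtype_jitter_sd > 0.0:
                delta_share = delta_share - rng.normal(0.0, subtype_jitter_sd, n_subj)
            new_from = np.clip(share_matrix[:, i_from] - delta_share, 0.0, 1.0)
            moved = share_matrix[:, i_from] - new_from
            share_matrix[:, i_from] = new_from
            share_matrix[:, i_to] = np.clip(share_matrix[:, i_to] + moved, 0.0, 1.0)
            subtype_share_record[shift_subtypes[0]] = share_matrix[:, i_from].copy()
            subtype_share_record[shift_subtypes[1]] = share_matrix[:, i_to].copy()
        L = leaf_profiles[leaves].to_numpy()  # n_cpgs x n_leaves
        pure[spec.name] = L @ share_matrix.T  # n_cpgs x n_subj

    # direct effects: add delta to smokers' profile before mixing
    for eff in effects:
        if eff.mechanism != "direct":
            continue
        targets = type_names if eff.cell_type == "all" else [eff.cell_type]
        i = cpg_index[eff.cpg_id]
        for t in targets:
            pure[t][i, smoker] = np.clip(pure[t][i, smoker] + eff.delta, 0.0, 1.0)

    # assemble fractions
    matrices: dict[str, np.ndarray] = {}
    mean_norm = mean_props / mean_props.sum()
    for k, spec in enumerate(specs):
        own = pure[spec.name]
        if spec.purity >= 1.0:
            frac = own
        else:
            others = [l for l in range(len(specs)) if l != k]
            weights = mean_norm[others] / mean_norm[others].sum()
            contaminant = np.zeros_like(own)
            for weight, l in zip(weights, others):
                contaminant += weight * pure[specs[l].name]
            frac = spec.purity * own + (1.0 - spec.purity) * contaminant
        matrices[spec.name] = frac
    wb = np.zeros((n_cpgs, n_subj))
    for k, spec in enumerate(specs):
        wb += w[:, k][None, :] * pure[spec.name]
    matrices["WB"] = wb

    # measurement noise on the M scale, then clamp
    out: dict[str, BetaMatrix] = {}
    for fraction in [*type_names, "WB"]:
        values = matrices[fraction]
        if noise_sd > 0:
            m = _to_m(values) + rng.normal(0.0, noise_sd, values.shape)
            values = _from_m(m)
        else:
            values = np.clip(values, BETA_EPS, 1.0 - BETA_EPS)
        samples = [f"{s}-{fraction}" for s in subjects]
        out[fraction] = BetaMatrix(
            pd.DataFrame(values, index=pd.Index(cpg_ids, name="cpg_id"), columns=samples)
        )

    sheet_rows = []
    for fraction in [*type_names, "WB"]:
        for j, subject in enumerate(subjects):
            sheet_rows.append(
                {
                    "sample_id": f"{subject}-{fraction}",
                    "subject_id": subject,
                    "fraction": fraction,
                    "smoking": int(cohort["smoking"].iloc[j]),
                    "age": float(cohort["age"].iloc[j]),
                    "sex": cohort["sex"].iloc[j],
                    "ancestry": cohort["ancestry"].iloc[j],
                    "bmi": float(cohort["bmi"].iloc[j]),
                }
            )
    sheet = SampleSheet(pd.DataFrame(sheet_rows))

    truth = TruthBundle(
        true_proportions=pd.DataFrame(
            w, index=pd.Index(subjects, name="subject_id"), columns=type_names
        ),
        true_subtype_shares=(
            pd.DataFrame(subtype_share_record, index=pd.Index(subjects, name="subject_id"))
            if subtype_share_record
            else None
        ),
        true_effects=list(effects),
    )
    truth.validate_ids(cpg_ids)
    return out, sheet, truth
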