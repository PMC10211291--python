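"""Desk-scale reproduction scenarios.

Self-contained routines that regenerate a seeded synthetic cohort,
run the relevant pipeline stages from scratch, and measure the headline
quantities: the genome-wide significance threshold, the composite
whole-blood decomposition correlation, and the naive-B subtype-shift
recovery. Used by ``scripts/acceptance.py`` and the acceptance tests.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from methylcell import composite as composite_mod
from methylcell import deconv, ewas, synthcohort

PROBE_COUNT = 420_000  # probes remaining after exclusions

# study group sizes and the reported naive-B shift
N_NONSMOKERS = 74
N_SMOKERS = 67
NAIVE_B_SHIFT = 0.072


def bonferroni_printed_threshold() -> float:
    """0.05 / probe count, rounded to two significant figures."""
    return ewas.bonferroni_threshold(PROBE_COUNT, alpha=0.05, sig_figs=2)


# ---------------------------------------------------------------------------
# composite decomposition
# ---------------------------------------------------------------------------

def _pure_specs():
    """The six cell types at purity 1 with no subtype structure."""
    return tuple(
        dataclasses.replace(s, purity=1.0, subtypes=())
        for s in synthcohort.default_cell_type_specs()
    )


def _mixed_origin_effects(panel, n_effects, seed, delta_min=0.02, delta_max=0.15):
    """Smoking effects of mixed cell-type origin on non-signature CpGs."""
    rng = np.random.default_rng(seed)
    signature = set()
    for ids in (panel.signature or {}).values():
        signature.update(ids)
    candidates = [c for c in panel.profiles.index if c not in signature]
    chosen = rng.choice(candidates, size=n_effects, replace=False)
    origins = ["all", "Gran", "Mono", "Bcell", "CD4T", "CD8T", "NK"]
    weights = np.array([0.34, 0.22, 0.10, 0.14, 0.08, 0.06, 0.06])
    effects = []
    for cpg in chosen:
        origin = rng.choice(origins, p=weights / weights.sum())
        magnitude = rng.uniform(delta_min, delta_max)
        sign = -1.0 if rng.random() < 0.75 else 1.0
        effects.append(synthcohort.EffectSpec(str(cpg), origin, sign * magnitude))
    return tuple(effects)


def composite_recovery(
    seed: int,
    n_cpgs: int = 900,
    n_effects: int = 74,
    noise_sd: float = 0.1,
    dirichlet_conc: float = 200.0,
) -> dict:
    """Simulate the cohort at purity 1, run all seven EWAS, and correlate
    the proportion-weighted composite with the whole-blood effect at the
    whole-blood Bonferroni-significant CpGs.

    Returns {"r": ..., "p": ..., "n_significant": ..., "n_cpgs": ...}.
    """
    specs = _pure_specs()
    panel, _ = synthcohort.make_reference_panel(
        n_cpgs=n_cpgs, specs=specs, n_signature_per_type=10, seed=seed
    )
    cohort = synthcohort.make_cohort(N_NONSMOKERS, N_SMOKERS, seed=seed + 1)
    effects = _mixed_origin_effects(panel, n_effects, seed + 2)
    matrices, sheet, _ = synthcohort.simulate_methylomes(
        panel,
        cohort,
        specs,
        effects=effects,
        shift=0.0,
        noise_sd=noise_sd,
        seed=seed + 3,
        dirichlet_conc=dirichlet_conc,
    )
    deltas = {}
    tables = {}
    for fraction, beta in matrices.items():
        m = ewas.mvalue_transform(beta)
        # purity 1: no contaminant proportions to adjust for
        table = ewas.fit_ewas(m, beta, sheet)
        table = ewas.multiple_testing(table)
        tables[fraction] = table.set_index("cpg_id")
        deltas[fraction] = tables[fraction]["delta_meth"]
    delta_df = pd.DataFrame({s.name: deltas[s.name] for s in specs})
    comp = composite_mod.composite_delta(delta_df, composite_mod.CompositeWeights(), "all")
    wb = tables["WB"]
    significant = wb.index[wb["bonferroni"]]
    stats = composite_mod.compare_to_wholeblood(comp, wb["delta_meth"], significant)
    return {
        "r": stats["r"],
        "p": stats["p"],
        "n_significant": int(len(significant)),
        "n_cpgs": n_cpgs,
    }


# ---------------------------------------------------------------------------
# naive-B shift recovery
# ---------------------------------------------------------------------------

def naive_shift_recovery(
    seed: int,
    n_seeds: int = 20,
    n_cpgs: int = 360,
    noise_sd: float = 0.1,
    shift: float = NAIVE_B_SHIFT,
    subtype_jitter_sd: float = 0.06,
) -> dict:
    """Recover the injected naive-B reduction by deconvolution.

    For each of ``n_seeds`` seeds, simulates the isolated B fraction
    with the configured group means, estimates 12-subtype proportions by
    constrained projection, and records the smoker-minus-nonsmoker
    difference in mean naive-B percent. Returns the mean recovered
    reduction (percentage points, positive), its Monte-Carlo SE, and
    the injected value.
    """
    specs = synthcohort.default_cell_type_specs()
    diffs = []
    for k in range(n_seeds):
        run_seed = seed + 1000 * k
        panel, _ = synthcohort.make_reference_panel(
            n_cpgs=n_cpgs, specs=specs, n_signature_per_type=10, seed=run_seed
        )
        cohort = synthcohort.make_cohort(N_NONSMOKERS, N_SMOKERS, seed=run_seed + 1)
        matrices, sheet, _ = synthcohort.simulate_methylomes(
            panel,
            cohort,
            specs,
            effects=(),
            shift=shift,
            noise_sd=noise_sd,
            seed=run_seed + 2,
            subtype_jitter_sd=subtype_jitter_sd,
        )
        signature = deconv.select_signature_cpgs(panel, 10)
        props = deconv.estimate_proportions(matrices["Bcell"], signature)
        result = deconv.subtype_shift_test(props, sheet.for_fraction("Bcell"), "NaiveB")
        diffs.append(result.diff)
    diffs = np.asarray(diffs)
    return {
        "recovered_reduction": float(-diffs.mean()),
        "mc_se": float(diffs.std(ddof=1) / np.sqrt(n_seeds)),
        "injected_reduction": 100.0 * shift,
        "n_seeds": n_seeds,
    }
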