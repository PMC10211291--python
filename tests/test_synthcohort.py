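"""Generator tests: bookkeeping, determinism, and analytic recovery."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methylcell import synthcohort
from methylcell.methio.core import ValidationError
from methylcell.synthcohort import (
    CellTypeSpec,
    EffectSpec,
    make_cohort,
    make_reference_panel,
    simulate_methylomes,
)
from methylcell.synthcohort.genetics import simulate_genetics, simulate_genotypes
from methylcell.synthcohort.panel import collapse_to_types


def six_plain_specs():
    return tuple(
        CellTypeSpec(name, prop)
        for name, prop in [
            ("Bcell", 0.073),
            ("Gran", 0.55),
            ("Mono", 0.037),
            ("NK", 0.060),
            ("CD4T", 0.20),
            ("CD8T", 0.087),
        ]
    )


class TestReferencePanel:
    def test_counts(self):
        panel, annot = make_reference_panel(600, six_plain_specs(), 20, seed=1)
        assert panel.profiles.shape == (600, 6)
        assert sum(len(v) for v in panel.signature.values()) == 120
        assert len(annot.df) == 600

    def test_determinism(self):
        a, annot_a = make_reference_panel(300, six_plain_specs(), 10, seed=7)
        b, annot_b = make_reference_panel(300, six_plain_specs(), 10, seed=7)
        pd.testing.assert_frame_equal(a.profiles, b.profiles)
        pd.testing.assert_frame_equal(annot_a.df, annot_b.df)
        assert a.signature == b.signature

    def test_signature_separation(self):
        panel, _ = make_reference_panel(600, six_plain_specs(), 20, seed=3)
        for cell_type, cpgs in panel.signature.items():
            own = panel.profiles.loc[cpgs, cell_type]
            others = panel.profiles.loc[cpgs].drop(columns=cell_type)
            gap = (own.to_numpy()[:, None] - others.to_numpy())
            assert (np.abs(gap).min(axis=1) >= 0.5).all()

    def test_positions_sorted_unique(self):
        _, annot = make_reference_panel(300, six_plain_specs(), 10, seed=3)
        pos = annot.df["pos"].to_numpy()
        assert (np.diff(pos) > 0).all()

    def test_seed_required(self):
        with pytest.raises(ValidationError, match="seed"):
            make_reference_panel(300, six_plain_specs(), 10, seed=None)

    def test_duplicate_names_rejected(self):
        specs = (CellTypeSpec("A", 0.5), CellTypeSpec("A", 0.5))
        with pytest.raises(ValidationError, match="duplicate"):
            make_reference_panel(100, specs, 5, seed=1)

    def test_too_few_cpgs_rejected(self):
        with pytest.raises(ValidationError, match="n_cpgs"):
            make_reference_panel(50, six_plain_specs(), 20, seed=1)


class TestCohort:
    def test_study_sizes(self):
        cohort = make_cohort(74, 67, seed=2)
        assert len(cohort) == 141
        assert int(cohort["smoking"].sum()) == 67

    def test_minimal(self):
        assert len(make_cohort(2, 2, seed=0)) == 4

    def test_counts_validated(self):
        with pytest.raises(ValidationError):
            make_cohort(1, 5, seed=0)

    def test_covariate_means_lln(self):
        # oracle: censored-normal mean (mass piles at the clip bounds)
        cohort = make_cohort(500, 500, seed=11)
        for col, mu, sd, (a, b) in [
            ("age", 40.0, 12.0, (18.0, 70.0)),
            ("bmi", 27.0, 5.0, (16.0, 50.0)),
        ]:
            alpha, beta_ = (a - mu) / sd, (b - mu) / sd
            expected = (
                a * stats.norm.cdf(alpha)
                + b * stats.norm.sf(beta_)
                + mu * (stats.norm.cdf(beta_) - stats.norm.cdf(alpha))
                - sd * (stats.norm.pdf(beta_) - stats.norm.pdf(alpha))
            )
            se = sd / np.sqrt(1000)
            assert abs(cohort[col].mean() - expected) < 3 * se

    def test_determinism(self):
        pd.testing.assert_frame_equal(make_cohort(10, 10, seed=5), make_cohort(10, 10, seed=5))


class TestMethylomes:
    def test_degenerate_equals_reference(self):
        specs = six_plain_specs()
        panel, _ = make_reference_panel(200, specs, 5, seed=4)
        cohort = make_cohort(3, 3, seed=4)
        matrices, _, _ = simulate_methylomes(
            panel, cohort, specs, noise_sd=0.0, seed=4
        )
        for spec in specs:
            expected = panel.profiles[spec.name].to_numpy()
            values = matrices[spec.name].df.to_numpy()
            assert np.allclose(values, expected[:, None], atol=1e-12)

    def test_mixture_identity_at_fixed_proportions(self):
        specs = six_plain_specs()
        panel, _ = make_reference_panel(200, specs, 5, seed=5)
        cohort = make_cohort(3, 3, seed=5)
        matrices, _, _ = simulate_methylomes(
            panel, cohort, specs, noise_sd=0.0, seed=5, dirichlet_conc=np.inf
        )
        w = np.array([s.mean_proportion for s in specs])
        w = w / w.sum()
        expected = panel.profiles.to_numpy() @ w
        assert np.allclose(matrices["WB"].df.to_numpy(), expected[:, None], atol=1e-12)

    def test_mixture_consistency_with_truth(self):
        specs = six_plain_specs()
        panel, _ = make_reference_panel(200, specs, 5, seed=6)
        cohort = make_cohort(4, 4, seed=6)
        matrices, _, truth = simulate_methylomes(
            panel, cohort, specs, noise_sd=0.0, seed=6
        )
        w = truth.true_proportions.to_numpy()
        mix = np.zeros(matrices["WB"].df.shape)
        for k, spec in enumerate(specs):
            mix += w[:, k][None, :] * matrices[spec.name].df.to_numpy()
        assert np.abs(mix - matrices["WB"].df.to_numpy()).max() <= 1e-12

    def test_true_proportions_simplex(self):
        specs = six_plain_specs()
        panel, _ = make_reference_panel(120, specs, 3, seed=8)
        cohort = make_cohort(10, 10, seed=8)
        _, _, truth = simulate_methylomes(panel, cohort, specs, seed=8)
        w = truth.true_proportions.to_numpy()
        assert (w >= 0).all()
        assert np.allclose(w.sum(axis=1), 1.0, atol=1e-9)

    def test_betas_clamped(self, specs, small_panel, small_cohort):
        panel, _ = small_panel
        matrices, _, _ = simulate_methylomes(
            panel, small_cohort, specs, noise_sd=0.5, shift=0.072, seed=9
        )
        for beta in matrices.values():
            values = beta.df.to_numpy()
            assert values.min() >= 1e-6 and values.max() <= 1 - 1e-6

    def test_direct_effect_recovery(self):
        # smoker-minus-nonsmoker mean at the target CpG ~= delta * purity
        specs = tuple(
            dataclasses.replace(s, subtypes=()) for s in synthcohort.default_cell_type_specs()
        )
        panel, _ = make_reference_panel(150, specs, 4, seed=10)
        target = next(c for c in panel.profiles.index if panel.profiles.loc[c, "Bcell"] > 0.3 and panel.profiles.loc[c, "Bcell"] < 0.7)
        cohort = make_cohort(60, 60, seed=10)
        noise_sd = 0.05
        matrices, _, _ = simulate_methylomes(
            panel,
            cohort,
            specs,
            effects=(EffectSpec(target, "Bcell", -0.10),),
            noise_sd=noise_sd,
            seed=10,
        )
        b = matrices["Bcell"].df.loc[target].to_numpy()
        smoking = cohort["smoking"].to_numpy() == 1
        observed = b[smoking].mean() - b[~smoking].mean()
        purity = specs[0].purity
        # beta-scale noise SE via the logistic derivative bound ln2 * 0.25
        se = 3 * noise_sd * np.log(2) * 0.25 * np.sqrt(1 / 60 + 1 / 60)
        assert observed == pytest.approx(-0.10 * purity, abs=3 * se + 0.01)

    def test_unknown_effect_rejected(self, specs, small_panel, small_cohort):
        panel, _ = small_panel
        with pytest.raises(ValidationError, match="unknown CpG"):
            simulate_methylomes(
                panel, small_cohort, specs, effects=(EffectSpec("cgNOPE", "Bcell", 0.1),), seed=1
            )
        with pytest.raises(ValidationError, match="unknown cell type"):
            simulate_methylomes(
                panel,
                small_cohort,
                specs,
                effects=(EffectSpec(panel.cpg_ids[0], "Tcell", 0.1),),
                seed=1,
            )

    def test_shift_moves_naive_to_memory(self, specs, small_panel, small_cohort):
        panel, _ = small_panel
        _, _, truth = simulate_methylomes(
            panel, small_cohort, specs, shift=0.072, noise_sd=0.0, seed=12
        )
        shares = truth.true_subtype_shares
        smoking = small_cohort.set_index("subject_id")["smoking"]
        naive_diff = (
            shares.loc[smoking == 1, "NaiveB"].mean()
            - shares.loc[smoking == 0, "NaiveB"].mean()
        )
        assert naive_diff == pytest.approx(-0.072 / 0.91, abs=1e-12)

    def test_determinism(self, specs, small_panel, small_cohort):
        panel, _ = small_panel
        a, _, _ = simulate_methylomes(panel, small_cohort, specs, seed=13)
        b, _, _ = simulate_methylomes(panel, small_cohort, specs, seed=13)
        for fraction in a:
            pd.testing.assert_frame_equal(a[fraction].df, b[fraction].df)


class TestCollapse:
    def test_type_profile_is_share_weighted_leaf_mix(self, specs, small_panel):
        panel, _ = small_panel
        types = collapse_to_types(panel, specs)
        b = specs[0]
        shares = b.lineage_shares()
        expected = sum(shares[l] * panel.profiles[l] for l in shares)
        pd.testing.assert_series_equal(types.profiles["Bcell"], expected, check_names=False)


@pytest.fixture(scope="module")
def annot():
    _, annot = make_reference_panel(200, six_plain_specs(), 5, seed=20)
    return annot


class TestGenetics:
    def test_complete_ld_duplicates_columns(self, annot):
        geno, blocks = simulate_genotypes(
            [f"S{i}" for i in range(40)], annot, n_blocks=2, snps_per_block=3,
            within_block_r2=1.0, seed=20,
        )
        for b in range(2):
            ids = blocks.loc[blocks["block"] == b, "snp_id"]
            dosages = geno.dosages.loc[ids].to_numpy()
            assert (dosages == dosages[0]).all()

    def test_maf_moment(self, annot):
        n = 400
        geno, blocks = simulate_genotypes(
            [f"S{i}" for i in range(n)], annot, n_blocks=4, snps_per_block=3,
            maf_range=(0.2, 0.4), within_block_r2=0.9, seed=21,
        )
        freq = geno.dosages.mean(axis=1) / 2.0
        for snp_id, maf in zip(blocks["snp_id"], blocks["maf"]):
            se = np.sqrt(maf * (1 - maf) / (2 * n))
            assert abs(freq[snp_id] - maf) < 4 * se

    def test_within_block_r2_hits_target(self, annot):
        n = 2000
        target = 0.8
        geno, blocks = simulate_genotypes(
            [f"S{i}" for i in range(n)], annot, n_blocks=3, snps_per_block=2,
            maf_range=(0.3, 0.5), within_block_r2=target, seed=22,
        )
        r2s = []
        for b in range(3):
            ids = blocks.loc[blocks["block"] == b, "snp_id"].tolist()
            d = geno.dosages.loc[ids].to_numpy(dtype=float)
            r2s.append(np.corrcoef(d[0], d[1])[0, 1] ** 2)
        assert np.mean(r2s) == pytest.approx(target, abs=0.1)

    def test_maf_range_validated(self, annot):
        with pytest.raises(ValidationError, match="maf_range"):
            simulate_genotypes(["S0", "S1"], annot, 1, 2, maf_range=(0.0, 0.6), seed=1)

    def test_null_mqtls_survive_nowhere(self, specs, small_panel, small_cohort):
        from methylcell.integrate import filter_mqtls

        panel, annot = small_panel
        matrices, _, _ = simulate_methylomes(panel, small_cohort, specs, seed=23)
        bundle = simulate_genetics(
            small_cohort, matrices["WB"], annot, n_blocks=3, snps_per_block=2,
            n_auto_mqtl=0, seed=23,
        )
        records = pd.concat(bundle.mqtl_tables.values())
        kept = filter_mqtls(records, annot, p_max=2e-11, min_studies=2)
        assert len(kept) == 0

    def test_unknown_effect_snp_rejected(self, specs, small_panel, small_cohort):
        panel, annot = small_panel
        matrices, _, _ = simulate_methylomes(panel, small_cohort, specs, seed=24)
        with pytest.raises(ValidationError, match="unknown SNP"):
            simulate_genetics(
                small_cohort, matrices["WB"], annot, n_blocks=2, snps_per_block=2,
                mqtl_specs=[("rsNOPE", annot.df["cpg_id"].iloc[0], 1.0)], seed=24,
            )

    def test_truth_recorded_and_valid(self, specs, small_panel, small_cohort):
        panel, annot = small_panel
        matrices, _, _ = simulate_methylomes(small_panel[0], small_cohort, specs, seed=25)
        bundle = simulate_genetics(
            small_cohort, matrices["WB"], annot, n_blocks=3, snps_per_block=2,
            n_auto_mqtl=2, seed=25,
        )
        assert len(bundle.truth.true_mqtl_pairs) == 2
        bundle.truth.validate_ids(
            matrices["WB"].cpg_ids, bundle.genotypes.snp_ids, bundle.gene_annot.df["gene_id"]
        )
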