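"""Integration filters: hand-counted fixtures, strict boundaries,
monotonicity, and order invariance."""

import numpy as np
import pandas as pd
import pytest

from methylcell import integrate
from methylcell.methio.core import CpGAnnotation, GeneAnnotation, GenotypeMatrix, ValidationError


@pytest.fixture
def annot():
    return CpGAnnotation(
        pd.DataFrame(
            {
                "cpg_id": ["cg1", "cg2", "cg3"],
                "chrom": ["chr1", "chr1", "chr2"],
                "pos": [50_000, 90_000, 5_000],
            }
        )
    )


def qtl(study, snp, pos, target, p, chrom="chr1", target_type="cpg"):
    return {
        "study_id": study,
        "snp_id": snp,
        "snp_chrom": chrom,
        "snp_pos": pos,
        "target_id": target,
        "target_type": target_type,
        "p": p,
    }


class TestFilterMqtls:
    def test_replication_in_two_of_four(self, annot):
        records = pd.DataFrame(
            [
                qtl("s1", "rsA", 52_000, "cg1", 1e-15),
                qtl("s2", "rsA", 52_000, "cg1", 0.5),
                qtl("s3", "rsA", 52_000, "cg1", 1e-20),
                qtl("s4", "rsA", 52_000, "cg1", 1e-3),
            ]
        )
        kept = integrate.filter_mqtls(records, annot)
        assert len(kept) == 1
        assert kept.iloc[0]["studies"] == "s1,s3"

    def test_distance_boundary_strict(self, annot):
        records = pd.DataFrame(
            [
                qtl("s1", "rsA", 60_000, "cg1", 1e-15),  # exactly 10 kb away
                qtl("s2", "rsA", 60_000, "cg1", 1e-15),
            ]
        )
        assert len(integrate.filter_mqtls(records, annot)) == 0
        records["snp_pos"] = 59_999
        assert len(integrate.filter_mqtls(records, annot)) == 1

    def test_p_boundary_strict(self, annot):
        records = pd.DataFrame(
            [qtl("s1", "rsA", 52_000, "cg1", 2e-11), qtl("s2", "rsA", 52_000, "cg1", 2e-11)]
        )
        assert len(integrate.filter_mqtls(records, annot)) == 0

    def test_five_record_toy(self, annot):
        records = pd.DataFrame(
            [
                qtl("s1", "rsA", 52_000, "cg1", 1e-15),  # passing pair, study 1
                qtl("s2", "rsA", 52_000, "cg1", 1e-13),  # passing pair, study 2
                qtl("s1", "rsB", 200_000, "cg1", 1e-15),  # too far
                qtl("s1", "rsC", 52_000, "cg1", 1e-9),  # weak p
                qtl("s1", "rsD", 91_000, "cg2", 1e-15),  # single study only
            ]
        )
        kept = integrate.filter_mqtls(records, annot)
        assert len(kept) == 1
        assert (kept.iloc[0]["cpg_id"], kept.iloc[0]["snp_id"]) == ("cg1", "rsA")

    def test_unknown_cpg_skipped(self, annot):
        records = pd.DataFrame(
            [qtl("s1", "rsA", 52_000, "cgX", 1e-15), qtl("s2", "rsA", 52_000, "cgX", 1e-15)]
        )
        assert len(integrate.filter_mqtls(records, annot)) == 0

    def test_chromosome_must_match(self, annot):
        records = pd.DataFrame(
            [
                qtl("s1", "rsA", 5_500, "cg3", 1e-15, chrom="chr1"),
                qtl("s2", "rsA", 5_500, "cg3", 1e-15, chrom="chr1"),
            ]
        )
        assert len(integrate.filter_mqtls(records, annot)) == 0

    def test_monotone_in_thresholds(self, annot):
        rng = np.random.default_rng(0)
        records = pd.DataFrame(
            [
                qtl(f"s{rng.integers(1, 5)}", f"rs{rng.integers(5)}",
                    int(50_000 + rng.integers(-15_000, 15_000)), "cg1",
                    float(10.0 ** -rng.uniform(5, 20)))
                for _ in range(60)
            ]
        )
        strict = integrate.filter_mqtls(records, annot, p_max=2e-11, dist_max=8_000)
        loose = integrate.filter_mqtls(records, annot, p_max=1e-8, dist_max=12_000)
        strict_pairs = set(map(tuple, strict[["cpg_id", "snp_id"]].to_numpy()))
        loose_pairs = set(map(tuple, loose[["cpg_id", "snp_id"]].to_numpy()))
        assert strict_pairs <= loose_pairs

    def test_order_invariance(self, annot):
        records = pd.DataFrame(
            [
                qtl("s1", "rsA", 52_000, "cg1", 1e-15),
                qtl("s2", "rsA", 52_000, "cg1", 1e-13),
                qtl("s1", "rsD", 91_000, "cg2", 1e-15),
                qtl("s2", "rsD", 91_000, "cg2", 1e-14),
            ]
        )
        a = integrate.filter_mqtls(records, annot)
        b = integrate.filter_mqtls(records.iloc[::-1].reset_index(drop=True), annot)
        pd.testing.assert_frame_equal(a, b)


class TestLdR2:
    def _geno(self, rows):
        dosages = pd.DataFrame(
            rows, index=pd.Index([f"rs{i}" for i in range(len(rows))], name="snp_id"),
            columns=[f"s{i}" for i in range(len(rows[0]))],
        )
        return GenotypeMatrix(dosages)

    def test_identical_vectors(self):
        geno = self._geno([[0, 0, 1, 1, 2, 2], [0, 0, 1, 1, 2, 2]])
        assert integrate.ld_r2(geno, "rs0", "rs1") == pytest.approx(1.0)

    def test_perfect_negative(self):
        geno = self._geno([[0, 0, 1, 1, 2, 2], [2, 2, 1, 1, 0, 0]])
        assert integrate.ld_r2(geno, "rs0", "rs1") == pytest.approx(1.0)

    def test_orthogonal(self):
        geno = self._geno([[0, 0, 1, 1, 2, 2], [0, 1, 0, 1, 0, 1]])
        assert integrate.ld_r2(geno, "rs0", "rs1") == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_error(self):
        geno = self._geno([[1, 1, 1, 1], [0, 1, 2, 0]])
        with pytest.raises(ValidationError, match="zero dosage variance"):
            integrate.ld_r2(geno, "rs0", "rs1")

    def test_matches_manual_dosage_correlation(self):
        rng = np.random.default_rng(1)
        rows = rng.integers(0, 3, size=(2, 8))
        geno = self._geno(rows.tolist())
        expected = np.corrcoef(rows[0], rows[1])[0, 1] ** 2
        assert integrate.ld_r2(geno, "rs0", "rs1") == pytest.approx(expected)


class TestFilterGwas:
    def _hits(self, rows):
        return pd.DataFrame(rows, columns=["snp_id", "chrom", "pos", "trait", "p", "n"])

    def test_boundaries_strict(self):
        hits = self._hits(
            [
                ["rs1", "chr1", 1, "t", 5e-8, 5000],  # p boundary
                ["rs2", "chr1", 2, "t", 1e-9, 1000],  # n boundary
                ["rs3", "chr1", 3, "t", 1e-9, 1001],
            ]
        )
        kept = integrate.filter_gwas(hits)
        assert list(kept["snp_id"]) == ["rs3"]

    def test_toy_counts(self):
        hits = self._hits(
            [
                ["rs1", "chr1", 1, "a", 1e-10, 5000],
                ["rs2", "chr1", 2, "b", 1e-6, 5000],
                ["rs3", "chr1", 3, "c", 1e-12, 500],
                ["rs4", "chr1", 4, "d", 1e-9, 2000],
            ]
        )
        assert len(integrate.filter_gwas(hits)) == 2

    def test_duplicates_collapse_to_min_p(self):
        hits = self._hits(
            [
                ["rs1", "chr1", 1, "t", 1e-10, 5000],
                ["rs1", "chr1", 1, "t", 1e-20, 6000],
            ]
        )
        kept = integrate.filter_gwas(hits)
        assert len(kept) == 1
        assert kept.iloc[0]["p"] == pytest.approx(1e-20)


class TestLinkGwas:
    def _geno(self):
        rng = np.random.default_rng(2)
        base = rng.integers(0, 3, 30)
        noisy = base.copy()
        noisy[:2] = (noisy[:2] + 1) % 3
        rows = {
            "rsP1": base,  # proxy, identical to rsG1
            "rsP2": noisy,  # proxy, high but imperfect LD with rsG1
            "rsP3": rng.integers(0, 3, 30),  # proxy, unlinked
            "rsG1": base,
        }
        dosages = pd.DataFrame(rows).T
        dosages.columns = [f"s{i}" for i in range(30)]
        dosages.index.name = "snp_id"
        return GenotypeMatrix(dosages)

    def _proxies(self, snps):
        return pd.DataFrame({"cpg_id": [f"cg{i}" for i, _ in enumerate(snps)], "snp_id": snps})

    def test_identity_link(self):
        geno = self._geno()
        gwas = pd.DataFrame(
            [["rsG1", "chr1", 1, "asthma", 1e-10, 5000]],
            columns=["snp_id", "chrom", "pos", "trait", "p", "n"],
        )
        links = integrate.link_gwas(self._proxies(["rsG1"]), gwas, geno)
        assert len(links) == 1 and links.iloc[0]["r2"] == 1.0

    def test_r2_boundary_strict(self):
        geno = self._geno()
        gwas = pd.DataFrame(
            [["rsG1", "chr1", 1, "asthma", 1e-10, 5000]],
            columns=["snp_id", "chrom", "pos", "trait", "p", "n"],
        )
        r2 = integrate.ld_r2(geno, "rsP2", "rsG1")
        links_above = integrate.link_gwas(
            self._proxies(["rsP2"]), gwas, geno, r2_threshold=r2 - 1e-9
        )
        links_at = integrate.link_gwas(
            self._proxies(["rsP2"]), gwas, geno, r2_threshold=r2
        )
        assert len(links_above) == 1 and len(links_at) == 0

    def test_block_fixture_enumeration(self):
        geno = self._geno()
        gwas = pd.DataFrame(
            [
                ["rsG1", "chr1", 1, "asthma", 1e-10, 5000],
                ["rsG2", "chr1", 2, "height", 1e-10, 5000],  # not genotyped
            ],
            columns=["snp_id", "chrom", "pos", "trait", "p", "n"],
        )
        links = integrate.link_gwas(
            self._proxies(["rsP1", "rsP2", "rsP3"]), gwas, geno, r2_threshold=0.5
        )
        # rsP1 (identical) and rsP2 (r2 > 0.5) link to rsG1; rsP3 does not;
        # rsG2 pairs are skipped for lack of genotypes
        assert len(links) == 2
        assert set(links["proxy_snp"]) == {"rsP1", "rsP2"}
        categories = set(links["category"])
        assert categories == {"other"}

    def test_trait_category_map(self):
        geno = self._geno()
        gwas = pd.DataFrame(
            [["rsG1", "chr1", 1, "asthma", 1e-10, 5000]],
            columns=["snp_id", "chrom", "pos", "trait", "p", "n"],
        )
        links = integrate.link_gwas(
            self._proxies(["rsG1"]), gwas, geno,
            trait_categories={"asthma": "disease risk"},
        )
        assert links.iloc[0]["category"] == "disease risk"


@pytest.fixture
def genes():
    return GeneAnnotation(
        pd.DataFrame(
            {
                "gene_id": ["G1"],
                "chrom": ["chr1"],
                "start": [10_000],
                "end": [20_000],
                "strand": ["+"],
            }
        )
    )


class TestFilterEqtm:
    def _records(self, cpg, pos, p, gene="G1"):
        return pd.DataFrame(
            [qtl("e1", cpg, pos, gene, p, target_type="gene")]
        )

    def _annot(self, pos):
        return CpGAnnotation(
            pd.DataFrame({"cpg_id": ["cgA"], "chrom": ["chr1"], "pos": [pos]})
        )

    def test_in_window(self, genes):
        kept = integrate.filter_eqtm(self._records("cgA", 5_000, 1e-8), self._annot(5_000), genes)
        assert len(kept) == 1

    def test_window_end_half_open(self, genes):
        # window is [start - 10 kb, end + 10 kb): position 30 000 excluded
        assert len(
            integrate.filter_eqtm(self._records("cgA", 30_000, 1e-8), self._annot(30_000), genes)
        ) == 0
        assert len(
            integrate.filter_eqtm(self._records("cgA", 29_999, 1e-8), self._annot(29_999), genes)
        ) == 1

    def test_window_start_closed(self, genes):
        assert len(
            integrate.filter_eqtm(self._records("cgA", 0, 1e-8), self._annot(0), genes)
        ) == 1

    def test_p_boundary_strict(self, genes):
        assert len(
            integrate.filter_eqtm(self._records("cgA", 5_000, 1e-5), self._annot(5_000), genes)
        ) == 0


class TestFilterEqtl:
    def _eqtl_records(self, snp_pos, p):
        return pd.DataFrame([qtl("q1", "rsA", snp_pos, "G1", p, target_type="gene")])

    def _proxies(self):
        return pd.DataFrame({"cpg_id": ["cgA"], "snp_id": ["rsA"]})

    def _annot(self, pos=15_000):
        return CpGAnnotation(
            pd.DataFrame({"cpg_id": ["cgA"], "chrom": ["chr1"], "pos": [pos]})
        )

    def test_kept_when_all_rules_pass(self, genes):
        kept = integrate.filter_eqtl(
            self._eqtl_records(15_000 + 9_000, 1e-6), self._proxies(), self._annot(), genes
        )
        assert len(kept) == 1

    def test_snp_too_far_from_cpg(self, genes):
        kept = integrate.filter_eqtl(
            self._eqtl_records(15_000 + 11_000, 1e-6), self._proxies(), self._annot(), genes
        )
        assert len(kept) == 0

    def test_cpg_outside_gene_window(self, genes):
        kept = integrate.filter_eqtl(
            self._eqtl_records(40_000, 1e-6), self._proxies(), self._annot(pos=45_000), genes
        )
        assert len(kept) == 0


class TestEvidenceTally:
    def test_hand_enumerated_order(self):
        evidence = pd.DataFrame(
            {
                "mqtl_s1": [1, 1, 0, 1, 1],
                "mqtl_s2": [1, 0, 0, 1, 1],
                "eqtm_e1": [1, 1, 0, 0, 1],
                "eqtl_q1": [1, 0, 0, 1, 1],
                "gwas_link": [0, 1, 0, 1, 0],
            },
            index=pd.Index([f"cg{i}" for i in range(5)], name="cpg_id"),
        )
        evidence["n_omics_layers"] = evidence.sum(axis=1)
        out = integrate.multi_omics_tally(evidence, min_layers=4)
        assert list(out.index) == ["cg0", "cg3", "cg4"]
        assert list(out["n_omics_layers"]) == [4, 4, 4]

    def test_min_layers_above_dataset_count(self):
        evidence = pd.DataFrame(
            {"mqtl_s1": [1], "n_omics_layers": [1]},
            index=pd.Index(["cg0"], name="cpg_id"),
        )
        out = integrate.multi_omics_tally(evidence, min_layers=4)
        assert len(out) == 0

    def test_flags_built_per_dataset(self):
        ev = integrate.evidence_table(
            ["cg0", "cg1"],
            mqtl_by_study={"s1": pd.DataFrame({"cpg_id": ["cg0"], "snp_id": ["rsA"]})},
            eqtm_evidence=pd.DataFrame(
                {"cpg_id": ["cg1"], "gene_id": ["G1"], "study_id": ["e1"], "p": [1e-9]}
            ),
            links=pd.DataFrame({"cpg_id": ["cg0"]}),
        )
        assert ev.loc["cg0", "mqtl_s1"] == 1
        assert ev.loc["cg1", "eqtm_e1"] == 1
        assert ev.loc["cg0", "n_omics_layers"] == 2
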