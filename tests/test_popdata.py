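import math

import numpy as np
import pandas as pd
import pytest

import aimpanel as ap
from aimpanel.popdata import PopdataError, hwe_exact_pvalue
from tests.conftest import marker_frame


class TestGenotypeIO:
    def test_vcf_dosages_and_missing(self, tmp_path):
        """GT fields 0/0, 0/1, 1/1 map to dosages 0, 1, 2; ./. is missing."""
        vcf = tmp_path / "toy.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ta\tb\tc\n"
            "1\t100\trs1\tA\tG\t.\t.\t.\tGT\t0/0\t0/1\t1/1\n"
            "2\t200\trs2\tC\tT\t.\t.\t.\tGT\t./.\t1/1\t0/0\n"
        )
        G = ap.read_genotypes(vcf)
        assert G.samples == ["a", "b", "c"]
        np.testing.assert_array_equal(G.dosages[:, 0], [0, 1, 2])
        assert math.isnan(G.dosages[0, 1])
        np.testing.assert_array_equal(G.dosages[1:, 1], [2, 0])
        assert G.markers.loc[1, "chrom"] == "2"

    def test_vcf_round_trip_preserves_everything(self, tmp_path, tiny_genotypes):
        ap.write_vcf(tiny_genotypes, tmp_path / "rt.vcf")
        back = ap.read_genotypes(tmp_path / "rt.vcf")
        assert back.samples == tiny_genotypes.samples
        assert back.marker_ids == tiny_genotypes.marker_ids
        np.testing.assert_array_equal(back.dosages, tiny_genotypes.dosages)
        pd.testing.assert_frame_equal(back.markers, tiny_genotypes.markers)

    def test_dosage_tsv_round_trip(self, tmp_path, tiny_genotypes):
        ap.write_dosage_tsv(tiny_genotypes, tmp_path / "d.tsv")
        back = ap.read_genotypes(tmp_path / "d.tsv", dialect="dosage")
        np.testing.assert_array_equal(back.dosages, tiny_genotypes.dosages)
        assert back.marker_ids == tiny_genotypes.marker_ids

    def test_multiallelic_rejected_or_skipped(self, tmp_path):
        vcf = tmp_path / "multi.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ta\n"
            "1\t100\trs1\tA\tG,T\t.\t.\t.\tGT\t0/1\n"
            "1\t200\trs2\tA\tG\t.\t.\t.\tGT\t1/1\n"
        )
        with pytest.raises(PopdataError, match="biallelic"):
            ap.read_genotypes(vcf)
        G = ap.read_genotypes(vcf, skip_multiallelic=True)
        assert G.marker_ids == ["rs2"]

    def test_duplicate_marker_ids_rejected(self):
        mk = marker_frame(2)
        mk.loc[1, "marker_id"] = "m0"
        with pytest.raises(PopdataError, match="duplicate"):
            ap.GenotypeMatrix(np.zeros((1, 2)), mk, ["s"])


class TestAlleleFrequencies:
    @pytest.mark.parametrize(
        "dosages, expected",
        [
            ([0, 0, 0], 0.0),
            ([2, np.nan], 1.0),  # missing excluded from denominator
            ([0, 1, 2, 1], 0.5),  # 4 ALT alleles over 8
        ],
    )
    def test_single_population_frequency(self, dosages, expected):
        dos = np.array(dosages, dtype=float)[:, None]
        G = ap.GenotypeMatrix(
            dos, marker_frame(1), [f"s{i}" for i in range(len(dosages))]
        )
        labels = {s: "pop" for s in G.samples}
        F = ap.allele_frequencies(G, labels)
        assert F.freqs[0, 0] == pytest.approx(expected)

    def test_no_calls_flagged_missing(self):
        dos = np.array([[np.nan], [np.nan]])
        G = ap.GenotypeMatrix(dos, marker_frame(1), ["a", "b"])
        F = ap.allele_frequencies(G, {"a": "p", "b": "p"})
        assert math.isnan(F.freqs[0, 0])

    def test_unknown_labelled_sample_errors(self, tiny_genotypes):
        with pytest.raises(PopdataError):
            ap.allele_frequencies(tiny_genotypes, {"ghost": "p"})

    def test_converges_to_generating_frequencies(self, small_cohort):
        """Reference sample frequencies approach true_F within 3 binomial SD."""
        co = small_cohort
        refs = sorted(co.reference_labels)
        F = ap.allele_frequencies(
            co.G.subset_samples(refs), co.reference_labels
        )
        n = co.config.n_reference_per_pop
        for pop in F.populations:
            p_hat = F.freqs[F.population_index(pop)]
            p = co.true_F.freqs[co.true_F.population_index(pop)]
            sd = np.sqrt(p * (1 - p) / (2 * n)) + 1e-9
            frac_within = np.mean(np.abs(p_hat - p) <= 3 * sd)
            assert frac_within > 0.98


class TestMafAndMissing:
    def test_maf_values(self, two_pop_freqs):
        got = ap.maf(two_pop_freqs)
        # pooled frequencies: 0.5, 0.3, 0.5, 0.5
        np.testing.assert_allclose(got, [0.5, 0.3, 0.5, 0.5])

    def test_maf_vector_arithmetic(self):
        mk = marker_frame(3)
        F = ap.FrequencyTable(np.array([[0.1, 0.9, 0.5]]), mk, ["p"])
        got = ap.maf(F)
        np.testing.assert_allclose(got, [0.1, 0.1, 0.5])
        assert np.mean(got) == pytest.approx(0.7 / 3)

    def test_missing_rate_counts(self, tiny_genotypes):
        overall, per_marker = ap.missing_rate(tiny_genotypes)
        assert overall == pytest.approx(1 / 12)
        np.testing.assert_allclose(per_marker, [0, 0.25, 0])

    def test_simulator_missing_rate_within_binomial_bound(self, small_cohort):
        rate = small_cohort.config.missing_rate
        n_entries = small_cohort.G.dosages.size
        overall, _ = ap.missing_rate(small_cohort.G)
        sd = math.sqrt(rate * (1 - rate) / n_entries)
        assert abs(overall - rate) < 3 * sd


class TestHWE:
    def test_exact_pvalue_against_enumeration_oracle(self):
        """Full conditional enumeration with rational arithmetic agrees."""
        from fractions import Fraction

        def oracle(aa, ab, bb):
            n = aa + ab + bb
            na = 2 * aa + ab
            # P(h) = 2^h n! / (h! ra! rb!) * na! (2n-na)! / (2n)!
            total = Fraction(0)
            pr = {}
            for h in range(na % 2, min(na, 2 * n - na) + 1, 2):
                ra = (na - h) // 2
                rb = n - h - ra
                if ra < 0 or rb < 0:
                    continue
                val = (
                    Fraction(2**h)
                    * Fraction(math.factorial(n), math.factorial(h))
                    / math.factorial(ra)
                    / math.factorial(rb)
                    * Fraction(
                        math.factorial(na) * math.factorial(2 * n - na),
                        math.factorial(2 * n),
                    )
                )
                pr[h] = val
                total += val
            assert total == 1
            obs = pr[ab]
            return float(sum(v for v in pr.values() if v <= obs))

        cases = [(25, 50, 25), (50, 0, 50), (3, 5, 2), (0, 1, 9), (10, 0, 0)]
        for aa, ab, bb in cases:
            assert hwe_exact_pvalue(aa, ab, bb) == pytest.approx(
                oracle(aa, ab, bb), rel=1e-9
            )

    def test_perfect_proportions_retained(self):
        assert hwe_exact_pvalue(25, 50, 25) > 1e-6

    def test_extreme_het_deficit_removed(self):
        assert hwe_exact_pvalue(50, 0, 50) < 1e-6


class TestQCFilter:
    def _matrix_with_call_rate(self, rate, n=100):
        rng = np.random.default_rng(0)
        dos = rng.binomial(2, 0.5, size=(n, 1)).astype(float)
        n_miss = round((1 - rate) * n)
        dos[:n_miss, 0] = np.nan
        return ap.GenotypeMatrix(dos, marker_frame(1), [f"s{i}" for i in range(n)])

    def test_low_call_rate_removed(self):
        G = self._matrix_with_call_rate(0.94)
        retained, report = ap.qc_filter(G, call_rate_min=0.95, hwe_alpha=0.0)
        assert retained == []
        assert report.loc[0, "rule"] == "call_rate"

    def test_hwe_violation_removed_in_any_population(self):
        dos = np.vstack([np.zeros((50, 1)), np.full((50, 1), 2.0)])
        G = ap.GenotypeMatrix(dos, marker_frame(1), [f"s{i}" for i in range(100)])
        labels = {s: "p1" for s in G.samples}
        retained, report = ap.qc_filter(G, 0.5, 1e-6, by_population=labels)
        assert retained == []
        assert report.loc[0, "rule"] == "hwe"

    def test_disabled_thresholds_retain_all(self, small_cohort):
        G = small_cohort.G
        retained, _ = ap.qc_filter(G, call_rate_min=1e-12, hwe_alpha=0.0,
                                   by_population=small_cohort.reference_labels)
        assert retained == G.marker_ids


class TestConcordance:
    def test_identity_and_symmetry(self, tiny_genotypes):
        overall, per_sample = ap.genotype_concordance(tiny_genotypes, tiny_genotypes)
        assert overall == 1.0
        assert (per_sample == 1.0).all()

    def test_one_mismatch_in_ten(self, tiny_genotypes):
        other = ap.GenotypeMatrix(
            tiny_genotypes.dosages.copy(),
            tiny_genotypes.markers,
            tiny_genotypes.samples,
        )
        other.dosages[0, 0] = 2.0  # was 0
        c12, _ = ap.genotype_concordance(tiny_genotypes, other)
        c21, _ = ap.genotype_concordance(other, tiny_genotypes)
        assert c12 == pytest.approx(10 / 11)  # 11 comparable pairs, 1 mismatch
        assert c12 == c21  # symmetric

    def test_missing_side_excluded_from_denominator(self):
        mk = marker_frame(2)
        G1 = ap.GenotypeMatrix(np.array([[0.0, 1.0]]), mk, ["s"])
        G2 = ap.GenotypeMatrix(np.array([[np.nan, 1.0]]), mk, ["s"])
        overall, _ = ap.genotype_concordance(G1, G2)
        assert overall == 1.0  # only the second marker compared

    def test_swapped_alleles_flipped(self):
        mk1 = marker_frame(1)
        mk2 = mk1.copy()
        mk2[["ref", "alt"]] = mk2[["alt", "ref"]].to_numpy()
        G1 = ap.GenotypeMatrix(np.array([[2.0], [0.0]]), mk1, ["s", "t"])
        G2 = ap.GenotypeMatrix(np.array([[0.0], [2.0]]), mk2, ["s", "t"])
        overall, _ = ap.genotype_concordance(G1, G2)
        assert overall == 1.0

    def test_no_overlap_errors(self, tiny_genotypes):
        other = ap.GenotypeMatrix(
            np.zeros((1, 3)), tiny_genotypes.markers, ["stranger"]
        )
        with pytest.raises(PopdataError):
            ap.genotype_concordance(tiny_genotypes, other)


class TestLD:
    def test_identical_and_anticorrelated_vectors(self):
        mk = marker_frame(3, spacing=100)
        dos = np.array(
            [[0, 0, 2], [1, 1, 1], [2, 2, 0], [0, 0, 2]], dtype=float
        )
        G = ap.GenotypeMatrix(dos, mk, list("abcd"))
        table = ap.ld_r2(G, window_bp=1000)
        r2 = table.set_index(["marker_a", "marker_b"])["r2"]
        assert r2[("m0", "m1")] == pytest.approx(1.0)
        assert r2[("m0", "m2")] == pytest.approx(1.0)  # perfect negative

    def test_hand_computed_pearson(self):
        x = np.array([0, 1, 2, 2], dtype=float)
        y = np.array([0, 0, 1, 2], dtype=float)
        # direct Pearson formula
        r = ((x - x.mean()) * (y - y.mean())).sum() / math.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        mk = marker_frame(2, spacing=100)
        G = ap.GenotypeMatrix(np.c_[x, y], mk, list("abcd"))
        table = ap.ld_r2(G, window_bp=1000)
        assert table["r2"].iloc[0] == pytest.approx(r**2)

    def test_window_and_monomorphic(self):
        mk = marker_frame(3, spacing=10_000)
        dos = np.array([[0, 1, 1], [1, 1, 0], [2, 1, 2]], dtype=float)
        G = ap.GenotypeMatrix(dos, mk, list("abc"))
        table = ap.ld_r2(G, window_bp=10_000)  # only adjacent pairs
        assert len(table) == 2
        assert table["r2"].isna().iloc[0]  # m1 monomorphic
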