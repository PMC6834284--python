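"""96-class mutation profiles, signature refitting and group statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import chi2_contingency, fisher_exact

from neep.mutsig import (build_profiles, classify_snv, compare_groups,
                         confounder_tests, fit_all, fit_contributions,
                         intersect_callers, moods_median_test, mutation_types,
                         read_maf, signature_enrichment_test)
from neep.synthetic import simulate_mutations, synthetic_signatures


def _catalog(rows):
    return pd.DataFrame(rows, columns=["patient_id", "caller", "chrom",
                                       "pos", "ref", "alt", "context"])


FOUR = ("muse", "mutect", "somaticsniper", "varscan")


class TestIntersectCallers:
    def test_consensus_requires_all_callers(self):
        rows = [("P1", c, "chr1", 100, "C", "T", "ACA") for c in FOUR]
        rows += [("P1", c, "chr1", 200, "C", "G", "ACA") for c in FOUR[:3]]
        consensus = intersect_callers(_catalog(rows), FOUR)
        assert len(consensus) == 1
        assert consensus.loc[0, "pos"] == 100

    def test_single_required_caller_is_identity(self):
        rows = [("P1", "muse", "chr1", 100, "C", "T", "ACA"),
                ("P1", "mutect", "chr1", 200, "C", "G", "ACA")]
        consensus = intersect_callers(_catalog(rows), {"muse"})
        assert len(consensus) == 1 and consensus.loc[0, "pos"] == 100

    def test_absent_required_caller_errors(self):
        rows = [("P1", "muse", "chr1", 100, "C", "T", "ACA")]
        with pytest.raises(ValueError, match="varscan"):
            intersect_callers(_catalog(rows), {"muse", "varscan"})


class TestClassify:
    def test_pyrimidine_reference_direct(self):
        assert classify_snv("C", "T", "ACA") == "A[C>T]A"

    def test_purine_reference_reverse_complemented(self):
        # G>T in context AGC reads C>A in context G_T on the other strand
        assert classify_snv("G", "T", "AGC") == "G[C>A]T"

    def test_non_acgt_context_returns_none(self):
        assert classify_snv("C", "T", "ANA") is None

    def test_bad_context_length_errors(self):
        with pytest.raises(ValueError):
            classify_snv("C", "T", "ACGA")

    @given(st.sampled_from(mutation_types()))
    def test_binning_is_involution_consistent(self, label):
        """Re-encoding a bin's representative mutation (on either strand)
        returns the same bin."""
        five, sub, three = label[0], label[2:5], label[6]
        ref, alt, ctx = sub[0], sub[2], five + sub[0] + three
        assert classify_snv(ref, alt, ctx) == label
        comp = str.maketrans("ACGT", "TGCA")
        assert classify_snv(ref.translate(comp), alt.translate(comp),
                            ctx.translate(comp)[::-1]) == label


class TestBuildProfiles:
    def test_counts_conserved(self):
        rows = [("P1", "x", "chr1", i, "C", "T", "ACA") for i in range(5)]
        rows += [("P1", "x", "chr1", 99, "G", "T", "AGC")]
        profiles, report = build_profiles(_catalog(rows).drop(columns="caller"))
        assert profiles.loc["P1"].sum() == 6 == len(rows)
        assert profiles.loc["P1", "A[C>T]A"] == 5
        assert profiles.loc["P1", "G[C>A]T"] == 1
        assert report["n_skipped_context"] == 0

    def test_zero_mutation_patient_all_zero(self):
        profiles, _ = build_profiles(
            _catalog([]).drop(columns="caller"), patients=["P9"])
        assert profiles.loc["P9"].sum() == 0

    def test_ambiguous_context_skipped_and_counted(self):
        rows = [("P1", "x", "chr1", 1, "C", "T", "NCA")]
        profiles, report = build_profiles(_catalog(rows).drop(columns="caller"))
        assert profiles.loc["P1"].sum() == 0
        assert report["n_skipped_context"] == 1


class TestFitContributions:
    def test_exact_noiseless_recovery(self):
        sigs = synthetic_signatures(4, seed=1)
        profile = 100 * sigs["S1"] + 50 * sigs["S3"]
        w = fit_contributions(profile, sigs)
        assert np.allclose(w, [100, 0, 50, 0], atol=1e-6)

    def test_zero_profile_zero_weights(self):
        sigs = synthetic_signatures(3, seed=1)
        assert np.allclose(fit_contributions(np.zeros(96), sigs), 0)

    def test_residual_zero_inside_nonnegative_span(self, rng):
        sigs = synthetic_signatures(5, seed=2)
        w_true = rng.uniform(0, 200, 5)
        profile = sigs.to_numpy() @ w_true
        w = fit_contributions(profile, sigs)
        assert np.allclose(sigs.to_numpy() @ w, profile, atol=1e-8)

    def test_multinomial_sample_recovers_proportions(self, rng):
        sigs = synthetic_signatures(2, seed=3)
        p = sigs.to_numpy() @ np.array([0.6, 0.4])
        profile = rng.multinomial(10_000, p / p.sum())
        w = fit_contributions(profile, sigs)
        props = w / w.sum()
        assert abs(props[0] - 0.6) < 0.05


class TestMoodsMedianTest:
    def test_identical_samples_p_one(self):
        res = moods_median_test([1, 2, 3], [1, 2, 3])
        assert res.p_value > 0.2  # symmetric table, no signal

    def test_degenerate_constant_data(self):
        res = moods_median_test([5, 5], [5, 5])
        assert res.p_value == 1.0 and res.degenerate

    def test_hand_table_and_exact_fallback(self):
        res = moods_median_test([1, 2, 3], [4, 5, 6])
        assert res.table == ((0, 3), (3, 0))
        # all expected cells are 1.5 < 5 -> Fisher's exact on the table
        assert res.method == "exact"
        assert res.p_value == pytest.approx(fisher_exact(res.table)[1])

    def test_group_swap_symmetry(self, rng):
        a, b = rng.normal(size=30), rng.normal(1, 1, size=30)
        assert moods_median_test(a, b).p_value == pytest.approx(
            moods_median_test(b, a).p_value)

    def test_large_sample_uses_uncorrected_chi2(self, rng):
        a, b = rng.normal(size=40), rng.normal(2, 1, size=40)
        res = moods_median_test(a, b)
        assert res.method == "chi2"
        ref_stat, ref_p, _, _ = chi2_contingency(np.array(res.table),
                                                 correction=False)
        assert res.statistic == pytest.approx(ref_stat)
        assert res.p_value == pytest.approx(ref_p)

    def test_matches_scipy_median_test_convention(self, rng):
        from scipy.stats import median_test
        a, b = rng.normal(size=45), rng.normal(0.8, 1, size=45)
        res = moods_median_test(a, b)
        stat, p, _, _ = median_test(a, b, ties="below", correction=False)
        assert res.p_value == pytest.approx(p)


class TestCompareGroups:
    def test_planted_shift_recovered(self, rng):
        contrib = pd.DataFrame({
            "S1": rng.normal(10, 1, 60),
            "S2": np.r_[rng.normal(10, 1, 30), rng.normal(16, 1, 30)]},
            index=[f"P{i}" for i in range(60)])
        labels = {f"P{i}": ("low" if i < 30 else "high") for i in range(60)}
        table = compare_groups(contrib, labels)
        s2 = table.set_index("signature").loc["S2"]
        assert s2["significant"]
        assert s2["mean_high_minus_low"] == pytest.approx(6, abs=1)
        assert not table.set_index("signature").loc["S1", "significant"]

    def test_single_patient_per_group_difference(self):
        contrib = pd.DataFrame({"S1": [3.0, 8.0]}, index=["a", "b"])
        table = compare_groups(contrib, {"a": "low", "b": "high"})
        assert table.loc[0, "mean_high_minus_low"] == pytest.approx(5.0)

    def test_empty_group_errors(self):
        contrib = pd.DataFrame({"S1": [1.0]}, index=["a"])
        with pytest.raises(ValueError):
            compare_groups(contrib, {"a": "low"})


class TestConfounderTests:
    def _frame(self, rng, n=40):
        cov = pd.DataFrame({
            "cigs_per_day": rng.normal(12, 3, 2 * n),
            "years_smoked": rng.integers(0, 40, 2 * n).astype(float),
            "smoker": rng.integers(0, 2, 2 * n).astype(float)},
            index=[f"P{i}" for i in range(2 * n)])
        labels = {f"P{i}": ("low" if i < n else "high") for i in range(2 * n)}
        return cov, labels

    def test_dispatch_by_kind(self, rng):
        cov, labels = self._frame(rng)
        out = confounder_tests(cov, labels, {"cigs_per_day": "metric",
                                             "years_smoked": "integer",
                                             "smoker": "binary"})
        assert set(out["variable"]) == set(cov.columns)
        assert out["p_value"].between(0, 1).all()

    def test_identical_groups_metric_p_near_one(self):
        cov = pd.DataFrame({"v": [1.0, 2, 3, 1, 2, 3]},
                           index=[f"P{i}" for i in range(6)])
        labels = {f"P{i}": ("low" if i < 3 else "high") for i in range(6)}
        out = confounder_tests(cov, labels, {"v": "metric"})
        assert out.loc[0, "p_value"] == pytest.approx(1.0)

    def test_binary_proportions_against_direct_computation(self):
        # 10/100 vs 50/100 successes
        vals = [1.0] * 10 + [0.0] * 90 + [1.0] * 50 + [0.0] * 50
        cov = pd.DataFrame({"b": vals}, index=[f"P{i}" for i in range(200)])
        labels = {f"P{i}": ("low" if i < 100 else "high") for i in range(200)}
        out = confounder_tests(cov, labels, {"b": "binary"})
        ref = chi2_contingency(np.array([[10, 90], [50, 50]]),
                               correction=True)[1]
        assert out.loc[0, "p_value"] == pytest.approx(ref)
        assert out.loc[0, "p_value"] < 1e-8

    def test_all_missing_variable_skipped_with_warning(self):
        cov = pd.DataFrame({"v": [np.nan, np.nan]}, index=["a", "b"])
        with pytest.warns(UserWarning, match="skipped"):
            out = confounder_tests(cov, {"a": "low", "b": "high"},
                                   {"v": "metric"})
        assert np.isnan(out.loc[0, "p_value"])

    def test_unknown_kind_errors(self):
        cov = pd.DataFrame({"v": [1.0]}, index=["a"])
        with pytest.raises(ValueError):
            confounder_tests(cov, {"a": "low"}, {"v": "ordinal"})


class TestEnrichment:
    def test_zero_hits_p_one(self):
        assert signature_enrichment_test(0, 10, 0.3) == 1.0

    def test_all_hits_closed_form(self):
        assert signature_enrichment_test(10, 10, 0.5) == pytest.approx(2 ** -10)

    def test_tail_sum_oracle(self):
        from math import comb
        p0, n, k = 0.05, 100, 5
        brute = sum(comb(n, i) * p0 ** i * (1 - p0) ** (n - i)
                    for i in range(k, n + 1))
        assert signature_enrichment_test(k, n, p0) == pytest.approx(brute)


class TestMafRoundTrip:
    def test_synthetic_maf_round_trips(self, tmp_path, rng):
        from neep.synthetic import write_maf
        sigs = synthetic_signatures(3, seed=4)
        w = rng.dirichlet(np.ones(3), size=2)
        catalog, _ = simulate_mutations(2, sigs, w, n_mutations=50,
                                        caller_dropout=0.0, seed=5)
        write_maf(catalog, tmp_path / "calls.maf")
        back = read_maf(tmp_path / "calls.maf")
        assert len(back) == len(catalog)
        consensus = intersect_callers(back, FOUR)
        assert len(consensus) == 100  # 2 patients x 50 mutations, no dropout

    def test_standard_maf_column_names(self, tmp_path):
        p = tmp_path / "std.maf"
        p.write_text("Tumor_Sample_Barcode\tChromosome\tStart_Position\t"
                     "Reference_Allele\tTumor_Seq_Allele2\tCaller\n"
                     "P1\tchr1\t100\tC\tT\tmuse\n"
                     "P1\tchr1\t101\tCT\tC\tmuse\n")  # indel dropped
        back = read_maf(p)
        assert len(back) == 1 and back.loc[0, "caller"] == "muse"
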