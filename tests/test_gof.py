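import json
import math

import numpy as np
import pytest
from scipy.integrate import quad

from digenic.gof import (
    DigenicTestResult,
    TestConfig,
    adjust_pvalues,
    chi2_gof,
    digenic_test,
    estimate_freqs_from_counts,
    write_results_json,
    write_results_tsv,
)
from digenic.gof import test_from_summary as summary_test  # avoid pytest collection
from digenic.hwe import GENOTYPE_LABELS, GenotypeCounts9


def oracle_chi2(observed, expected, df):
    """Textbook Pearson statistic + p by numeric integration of the density."""
    statistic = sum((o - e) ** 2 / e for o, e in zip(observed, expected))

    def density(x, k):
        return x ** (k / 2 - 1) * math.exp(-x / 2) / (2 ** (k / 2) * math.gamma(k / 2))

    p_value, _ = quad(density, statistic, math.inf, args=(df,))
    return statistic, p_value


class TestChi2Gof:
    def test_perfect_fit(self):
        statistic, p = chi2_gof([10, 20, 30], [10.0, 20.0, 30.0], df=2)
        assert statistic == 0.0
        assert p == 1.0

    def test_frozen_depletion_table(self):
        # values frozen from the oracle above (hand Pearson sum + integration)
        statistic, p = chi2_gof(
            [2, 3060, 97, 35182], [8.098, 3053.9, 90.9, 35188.1], df=1
        )
        assert statistic == pytest.approx(5.014541938022109, rel=1e-12)
        assert p == pytest.approx(0.025135278486922957, rel=1e-9)

    def test_df_sensitivity_at_critical_value(self):
        # two symmetric cells with deviation sqrt(192) give statistic 3.84
        d = math.sqrt(192.0)
        statistic, p = chi2_gof([100 + d, 100 - d], [100.0, 100.0], df=1)
        assert statistic == pytest.approx(3.84, rel=1e-12)
        assert p == pytest.approx(0.0500435212486994, rel=1e-9)

    def test_matches_oracle_on_random_tables(self, rng):
        for df in (1, 6):
            for _ in range(20):
                expected = rng.uniform(2.0, 500.0, size=df + 1)
                observed = expected + rng.normal(0, 3, size=df + 1)
                observed = np.clip(observed, 0.1, None)
                observed *= expected.sum() / observed.sum()
                statistic, p = chi2_gof(observed, expected, df=df)
                o_stat, o_p = oracle_chi2(observed, expected, df)
                assert statistic == pytest.approx(o_stat, abs=1e-10)
                assert p == pytest.approx(o_p, abs=1e-10)

    def test_zero_expected_names_category(self):
        with pytest.raises(ValueError, match="cocarriers"):
            chi2_gof([1, 2], [0.0, 3.0], df=1, labels=["cocarriers", "rest"])

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="categories"):
            chi2_gof([1, 2, 3], [1.0, 2.0], df=1)

    def test_total_mismatch(self):
        with pytest.raises(ValueError, match="total"):
            chi2_gof([10, 10], [50.0, 50.0], df=1)


def hwe_exact_counts_half():
    """9-class table exactly at HWE for q1=q2=0.5, N=16."""
    return GenotypeCounts9(np.array([1, 2, 1, 2, 4, 2, 1, 2, 1]))


class TestDigenicTest:
    def test_exact_hwe_table_gives_p_one(self):
        result = digenic_test(hwe_exact_counts_half(), TestConfig(min_expected_cocarriers=0))
        assert result.q1_hat == 0.5
        assert result.q2_hat == 0.5
        assert result.chi2_statistic == pytest.approx(0.0, abs=1e-12)
        assert result.p_value == pytest.approx(1.0)
        assert result.df == 1

    def test_allele_counting(self):
        # brute-force: 8 het + 1 hom-alt at VAR1 = 10 alt alleles over 2N=200
        counts = np.zeros(9)
        counts[GENOTYPE_LABELS.index("AABB")] = 91
        counts[GENOTYPE_LABELS.index("AaBB")] = 8
        counts[GENOTYPE_LABELS.index("aaBB")] = 1
        freqs = estimate_freqs_from_counts(GenotypeCounts9(counts))
        assert freqs.q1 == pytest.approx(0.05)
        assert freqs.q2 == 0.0

    def test_min_expected_rule(self):
        counts = np.zeros(9)
        counts[0] = 980
        counts[1] = 10
        counts[3] = 9
        counts[4] = 1
        result = digenic_test(GenotypeCounts9(counts), TestConfig(min_expected_cocarriers=5))
        # expected co-carriers well below 5 at these frequencies
        assert result.expected_cocarriers < 5
        assert not result.testable
        assert result.p_value is None
        assert "below minimum" in result.reason

    def test_monomorphic_flagged(self):
        counts = np.zeros(9)
        counts[GENOTYPE_LABELS.index("AaBB")] = 50
        counts[GENOTYPE_LABELS.index("AABB")] = 50
        result = digenic_test(GenotypeCounts9(counts))
        assert not result.testable
        assert result.reason == "monomorphic variant"

    def test_empty_cohort_errors(self):
        with pytest.raises(ValueError):
            digenic_test(GenotypeCounts9(np.zeros(9)))

    def test_modes_share_frequency_estimates(self, rng):
        counts = GenotypeCounts9(rng.multinomial(2000, np.full(9, 1 / 9)))
        collapsed = digenic_test(counts, TestConfig(mode="collapsed"))
        full = digenic_test(counts, TestConfig(mode="full"))
        assert collapsed.q1_hat == full.q1_hat
        assert collapsed.q2_hat == full.q2_hat
        assert collapsed.df == 1
        assert full.df == 6

    def test_difference_sign_preserved(self):
        result = summary_test(0.0415, 0.0013, 38341, 2)
        assert result.difference == pytest.approx(2 - result.expected_cocarriers)
        assert result.difference < 0
        assert result.depleted


class TestFromSummary:
    def test_observed_equals_expected(self):
        expected = 8.097036056490076  # hand value for this pair
        result = summary_test(0.0415, 0.0013, 38341, expected)
        assert result.p_value == pytest.approx(1.0)

    def test_depleted_rare_pair_significant(self):
        result = summary_test(0.0415, 0.0013, 38341, 2)
        assert result.p_value < 0.05
        assert result.imputed

    def test_concordant_pair_not_significant(self):
        result = summary_test(0.00334, 0.0735, 38341, 36)
        assert result.p_value > 0.9

    def test_observed_exceeding_n_errors(self):
        with pytest.raises(ValueError):
            summary_test(0.1, 0.1, 100, 101)

    def test_untestable_below_threshold(self):
        result = summary_test(0.001, 0.001, 1000, 0)
        assert not result.testable

    def test_boundary_frequencies_rejected(self):
        with pytest.raises(ValueError):
            summary_test(0.0, 0.1, 100, 0)


def _result(pair_id, p):
    return DigenicTestResult(
        pair_id=pair_id, q1_hat=0.1, q2_hat=0.1, n=100,
        observed_cocarriers=1, expected_cocarriers=2,
        chi2_statistic=1.0, df=1, p_value=p,
    )


class TestAdjustPvalues:
    def test_single_result_bh_unchanged(self):
        (out,) = adjust_pvalues([_result("a", 0.04)], "benjamini-hochberg")
        assert out.adjusted_p == pytest.approx(0.04)

    def test_bh_hand_example(self):
        results = [_result(str(i), p) for i, p in enumerate([0.01, 0.02, 0.03])]
        adjusted = [r.adjusted_p for r in adjust_pvalues(results, "benjamini-hochberg")]
        assert adjusted == pytest.approx([0.03, 0.03, 0.03])

    def test_bonferroni_hand_example(self):
        results = [_result(str(i), p) for i, p in enumerate([0.0237, 0.5, 0.6, 0.7, 0.8])]
        adjusted = adjust_pvalues(results, "bonferroni")
        assert adjusted[0].adjusted_p == pytest.approx(0.1185)

    def test_none_copies_p(self):
        (out,) = adjust_pvalues([_result("a", 0.2)], "none")
        assert out.adjusted_p == pytest.approx(0.2)

    def test_untestable_skipped(self):
        bad = _result("bad", None)
        bad.testable = False
        bad.p_value = None
        out = adjust_pvalues([_result("ok", 0.01), bad], "bonferroni")
        # only testable results enter the correction, so m = 1
        assert out[0].adjusted_p == pytest.approx(0.01)
        assert out[1].adjusted_p is None

    def test_unknown_method(self):
        with pytest.raises(ValueError, match="unknown method"):
            adjust_pvalues([_result("a", 0.1)], "holm")

    def test_input_not_mutated(self):
        original = _result("a", 0.04)
        adjust_pvalues([original], "bonferroni")
        assert original.adjusted_p is None


class TestWriters:
    def test_tsv_roundtrip(self, tmp_path):
        results = [_result("pairA", 0.01), _result("pairB", 0.9)]
        path = tmp_path / "out.tsv"
        write_results_tsv(results, path)
        lines = path.read_text().strip().split("\n")
        assert len(lines) == 3
        header = lines[0].split("\t")
        row = dict(zip(header, lines[1].split("\t")))
        assert row["pair"] == "pairA"
        assert row["significant"] == "*"
        assert float(row["diff"]) == pytest.approx(-1.0)

    def test_json_output(self, tmp_path):
        path = tmp_path / "out.json"
        write_results_json([_result("pairA", 0.01)], path)
        payload = json.loads(path.read_text())
        assert payload[0]["pair"] == "pairA"
        assert payload[0]["significant"] is True


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"mode": "bogus"},
            {"alpha": 0.0},
            {"alpha": 1.0},
            {"min_expected_cocarriers": -1},
            {"multiple_testing": "holm"},
        ],
    )
    def test_rejects_bad_config(self, kwargs):
        with pytest.raises(ValueError):
            TestConfig(**kwargs)
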