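"""Benchmarking statistics: smoothing, correlation, quartile labels, ROC/PR, Wilcoxon."""

import numpy as np
import pytest
from scipy import stats

from seqfrust.benchmark import (
    benchmark_report,
    correlation,
    normalize,
    paired_differences,
    quartile_labels,
    roc_pr,
    smooth,
    wilcoxon_greater,
)
from seqfrust.errors import StatisticsError, ValidationError

NAN = np.nan


class TestSmooth:
    def test_window_one_identity(self):
        v = np.array([1.0, NAN, 3.0])
        assert np.array_equal(smooth(v, 1), v, equal_nan=True)

    def test_constant_unchanged(self):
        v = np.full(9, 2.5)
        assert np.array_equal(smooth(v, 5), v)

    def test_edge_shrink(self):
        v = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        assert np.allclose(smooth(v, 3), [1.5, 2.0, 3.0, 4.0, 4.5])

    def test_masked_positions_stay_masked_and_are_skipped(self):
        v = np.array([1.0, NAN, 3.0, 5.0])
        out = smooth(v, 3)
        assert np.isnan(out[1])
        assert out[0] == 1.0  # only itself defined in its window
        assert out[2] == 4.0  # (3+5)/2, NaN neighbor skipped

    @pytest.mark.parametrize("window", [0, 2, -3])
    def test_bad_window(self, window):
        with pytest.raises(ValidationError):
            smooth(np.ones(5), window)


class TestNormalize:
    def test_zscore_moments(self):
        rng = np.random.default_rng(0)
        v = rng.normal(5, 3, 50)
        v[7] = NAN
        z = normalize(v, "zscore")
        d = z[~np.isnan(z)]
        assert d.mean() == pytest.approx(0.0, abs=1e-12)
        assert d.std(ddof=0) == pytest.approx(1.0, rel=1e-12)

    def test_minmax_example(self):
        assert np.allclose(normalize(np.array([2.0, 4.0, 6.0]), "minmax"), [0, 0.5, 1])

    def test_rank_order_preserved(self):
        rng = np.random.default_rng(1)
        v = rng.normal(size=30)
        order = np.argsort(v)
        for method in ("zscore", "minmax"):
            assert np.array_equal(np.argsort(normalize(v, method)), order)

    def test_zero_variance_error(self):
        with pytest.raises(StatisticsError):
            normalize(np.full(5, 3.0), "zscore")


class TestCorrelation:
    def test_perfect_and_reversed(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        assert correlation(x, x)[0] == pytest.approx(1.0)
        assert correlation(x, -x)[0] == pytest.approx(-1.0)

    def test_tied_data_matches_rank_then_pearson_oracle(self):
        x = np.array([1.0, 2.0, 2.0, 3.0])
        y = np.array([10.0, 20.0, 30.0, 40.0])
        rho, _, n = correlation(x, y)
        # explicit average-rank computation, then Pearson
        rx = np.array([1.0, 2.5, 2.5, 4.0])
        ry = np.array([1.0, 2.0, 3.0, 4.0])
        expected = np.corrcoef(rx, ry)[0, 1]
        assert rho == pytest.approx(expected, abs=1e-12)
        assert n == 4

    def test_symmetry_both_methods(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=20), rng.normal(size=20)
        for method in ("spearman", "pearson"):
            assert correlation(x, y, method)[0] == pytest.approx(correlation(y, x, method)[0])

    def test_spearman_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=25), rng.normal(size=25)
        rho0 = correlation(x, y)[0]
        assert correlation(np.exp(x), y)[0] == pytest.approx(rho0, abs=1e-12)
        assert correlation(x, 5 * y - 2)[0] == pytest.approx(rho0, abs=1e-12)

    def test_pairwise_deletion_of_masks(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, NAN])
        y = np.array([1.0, 2.0, 3.0, NAN, 5.0])
        rho, _, n = correlation(x, y)
        assert n == 3 and rho == pytest.approx(1.0)

    def test_preconditions(self):
        with pytest.raises(StatisticsError):
            correlation([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(StatisticsError):
            correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_exact_permutation_p_small_n(self):
        # n=4 identical vectors: only 1 of 24 permutations reaches rho=1
        x = np.array([1.0, 2.0, 3.0, 4.0])
        _, p, _ = correlation(x, x, alternative="greater", exact=True)
        assert p == pytest.approx(1 / 24)

    def test_pearson_alternative_one_sided(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=15)
        y = x + rng.normal(scale=0.3, size=15)
        rho, p, _ = correlation(x, y, method="pearson", alternative="greater")
        r2, p2 = stats.pearsonr(x, y, alternative="greater")
        assert (rho, p) == (pytest.approx(r2), pytest.approx(p2))


class TestQuartileLabels:
    def test_one_through_eight(self):
        labels = quartile_labels(np.arange(1.0, 9.0))
        assert list(labels) == ["low", "low", "mid", "mid", "mid", "mid", "high", "high"]

    def test_degenerate_spread_error(self):
        with pytest.raises(StatisticsError):
            quartile_labels(np.full(10, 1.0))

    def test_too_few_defined(self):
        with pytest.raises(StatisticsError):
            quartile_labels(np.array([1.0, 2.0, 3.0, NAN, NAN, NAN, NAN, NAN]))

    def test_balanced_counts_continuous_data(self):
        rng = np.random.default_rng(5)
        v = rng.normal(size=200)
        labels = quartile_labels(v)
        assert abs((labels == "high").sum() - 50) <= 1
        assert abs((labels == "low").sum() - 50) <= 1

    def test_masked_unlabeled(self):
        v = np.append(np.arange(1.0, 9.0), NAN)
        assert quartile_labels(v)[-1] is None


class TestRocPr:
    def _labels(self, n_high, n_low):
        return np.array(["high"] * n_high + ["low"] * n_low, dtype=object)

    def test_perfect_ordering(self):
        labels = self._labels(3, 3)
        score = np.array([5.0, 4.0, 3.0, 2.0, 1.0, 0.0])
        auc, ap, base = roc_pr(score, labels, "high")
        assert (auc, ap, base) == (1.0, 1.0, 0.5)

    def test_reversed_ordering(self):
        labels = self._labels(3, 3)
        score = np.array([0.0, 1.0, 2.0, 3.0, 4.0, 5.0])
        assert roc_pr(score, labels, "high")[0] == 0.0

    def test_low_target_uses_negated_score(self):
        labels = self._labels(3, 3)
        score = np.array([5.0, 4.0, 3.0, 2.0, 1.0, 0.0])
        auc, ap, _ = roc_pr(score, labels, "low")
        assert (auc, ap) == (1.0, 1.0)

    def test_auc_complement_identity(self):
        rng = np.random.default_rng(6)
        labels = np.array(rng.choice(["high", "low", "mid"], size=60), dtype=object)
        score = rng.normal(size=60)
        auc_pos = roc_pr(score, labels, "high")[0]
        auc_neg = roc_pr(-score, labels, "high")[0]
        assert auc_pos == pytest.approx(1.0 - auc_neg)

    def test_mid_and_masked_excluded(self):
        labels = np.array(["high", "mid", "low", None, "high", "low"], dtype=object)
        score = np.array([3.0, 100.0, 1.0, 100.0, 4.0, 0.0])
        auc, ap, base = roc_pr(score, labels, "high")
        assert auc == 1.0 and base == 0.5

    def test_single_class_error(self):
        with pytest.raises(StatisticsError):
            roc_pr(np.array([1.0, 2.0]), np.array(["high", "high"], dtype=object), "high")


class TestPairedDifferences:
    def test_identical_zero(self):
        pc = paired_differences([0.3, 0.5], [0.3, 0.5])
        assert np.array_equal(pc.differences, [0.0, 0.0])

    def test_constant_shift(self):
        pc = paired_differences(np.array([0.4, 0.6, 0.8]), np.array([0.3, 0.5, 0.7]))
        assert np.allclose(pc.differences, 0.1)
        assert pc.mean == pytest.approx(0.1)

    def test_median_matches_sort_oracle(self):
        rng = np.random.default_rng(7)
        a, b = rng.normal(size=11), rng.normal(size=11)
        pc = paired_differences(a, b)
        assert pc.median == sorted(a - b)[5]

    def test_length_mismatch(self):
        with pytest.raises(ValidationError):
            paired_differences([0.1], [0.1, 0.2])


class TestWilcoxonGreater:
    def test_all_positive_n10_exact(self):
        values = 0.5 + np.arange(1, 11) / 100.0
        assert wilcoxon_greater(values, 0.5) == pytest.approx(1 / 1024)

    def test_symmetric_about_baseline(self):
        d = np.array([-4.0, -3.0, -2.0, -1.0, 1.0, 2.0, 3.0, 4.0])
        p = wilcoxon_greater(d + 0.5, 0.5)
        assert 0.4 <= p <= 0.6

    def test_matches_scipy_exact_oracle(self):
        rng = np.random.default_rng(8)
        d = rng.normal(0.2, 1.0, size=12)
        p = wilcoxon_greater(d + 1.0, 1.0)
        expected = stats.wilcoxon(d, alternative="greater", method="exact").pvalue
        assert p == pytest.approx(expected, abs=1e-12)

    def test_large_n_uses_normal_approximation(self):
        rng = np.random.default_rng(9)
        d = rng.normal(0.3, 1.0, size=40)
        p = wilcoxon_greater(d, 0.0)
        expected = stats.wilcoxon(d, alternative="greater", method="approx").pvalue
        assert p == pytest.approx(expected)

    def test_preconditions(self):
        with pytest.raises(StatisticsError):
            wilcoxon_greater(np.array([0.5, 0.5, 0.5]), 0.5)
        with pytest.raises(StatisticsError):
            wilcoxon_greater(np.array([0.6, 0.7, 0.4]), 0.5)


class TestMaskingConsistency:
    def test_adding_masked_position_changes_nothing(self):
        rng = np.random.default_rng(10)
        x, y = rng.normal(size=40), rng.normal(size=40)
        r1 = benchmark_report(x, y)
        x2, y2 = np.append(x, NAN), np.append(y, 3.0)
        r2 = benchmark_report(x2, y2)
        for key in ("rho", "p_value", "n_pairs", "auc_roc_high", "ap_high", "ap_low"):
            assert r1[key] == pytest.approx(r2[key], abs=1e-12), key


class TestBenchmarkReport:
    def test_self_comparison_rho_one(self):
        rng = np.random.default_rng(11)
        v = rng.normal(size=30)
        report = benchmark_report(v, v)
        assert report["rho"] == pytest.approx(1.0)
        assert report["auc_roc_high"] == 1.0
        assert report["baseline_high"] == pytest.approx(0.5, abs=0.1)

    def test_config_echoed(self):
        rng = np.random.default_rng(12)
        v, b = rng.normal(size=30), rng.normal(size=30)
        report = benchmark_report(v, b, window=3, normalization="zscore")
        assert report["config"]["window"] == 3
        assert report["config"]["normalization"] == "zscore"
        assert report["masking"]["n_positions"] == 30
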