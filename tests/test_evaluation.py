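"""Case labeling, ROC/AUC, DeLong inference and cohort-table statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bseeg_tda import (
    Assessment,
    DegenerateCohortError,
    auc,
    chi_square_2x2,
    delong_paired_test,
    label_delirium,
    specificity_at_sensitivity,
    two_sample_t,
    wilson_interval,
)
from bseeg_tda.evaluation import DegenerateTableError
from oracles import bootstrap_auc_diff_variance, brute_force_auc


class TestLabelDelirium:
    @pytest.mark.parametrize("assessment,expected", [
        (Assessment(drs=19.0), True),                      # DRS cut-off inclusive
        (Assessment(doss=3.0), True),                      # DOSS cut-off inclusive
        (Assessment(cam_icu_positive=True), True),
        (Assessment(chart_delirium=True), True),
        (Assessment(drs=18.0, doss=2.0), False),           # all below cut-offs
        (Assessment(), False),
    ])
    def test_case_definition(self, assessment, expected):
        assert label_delirium(assessment) is expected


class TestAuc:
    def test_three_of_four_pairs_concordant(self):
        result = auc([0.1, 0.4, 0.35, 0.8], [False, False, True, True])
        assert result.auc == pytest.approx(0.75)

    def test_perfect_separation(self):
        result = auc([0, 1, 2, 10, 11], [False, False, False, True, True])
        assert result.auc == 1.0

    def test_matches_brute_force_on_200_random_scores(self):
        rng = np.random.default_rng(17)
        scores = rng.normal(size=200)
        labels = rng.random(200) < 0.4
        result = auc(scores, labels)
        assert result.auc == brute_force_auc(scores, labels)

    def test_ties_counted_half(self):
        result = auc([1.0, 1.0], [True, False])
        assert result.auc == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateCohortError):
            auc([0.1, 0.2], [True, True])

    def test_complement_symmetry(self):
        rng = np.random.default_rng(18)
        scores = rng.normal(size=50)  # continuous: tie-free
        labels = rng.random(50) < 0.5
        assert auc(scores, labels).auc + auc(-scores, labels).auc == pytest.approx(1.0)

    @given(st.sampled_from(["exp", "cube", "affine"]))
    @settings(deadline=None)
    def test_invariant_under_monotone_transform(self, kind):
        rng = np.random.default_rng(19)
        scores = rng.normal(size=60)
        labels = rng.random(60) < 0.5
        transform = {"exp": np.exp, "cube": lambda x: x**3,
                     "affine": lambda x: 3 * x + 7}[kind]
        assert auc(transform(scores), labels).auc == pytest.approx(auc(scores, labels).auc)

    def test_ci_brackets_auc_and_shrinks_with_n(self):
        rng = np.random.default_rng(20)
        widths = []
        for n in (50, 200, 800):
            labels = np.arange(n) < n // 2
            scores = rng.normal(labels * 1.0, 1.0)
            result = auc(scores, labels)
            assert result.ci_low <= result.auc <= result.ci_high
            assert result.variance >= 0
            widths.append(result.ci_high - result.ci_low)
        assert widths[0] > widths[1] > widths[2]


class TestDelong:
    LABELS6 = np.array([1, 1, 1, 0, 0, 0], dtype=bool)
    A6 = np.array([0.9, 0.7, 0.4, 0.5, 0.3, 0.2])
    B6 = np.array([0.8, 0.6, 0.3, 0.45, 0.5, 0.1])

    def test_self_comparison_degenerate(self):
        res = delong_paired_test(self.A6, self.A6, self.LABELS6)
        assert res.auc_a == res.auc_b
        assert res.p == 1.0 and res.degenerate

    def test_swap_negates_z(self):
        fwd = delong_paired_test(self.A6, self.B6, self.LABELS6)
        rev = delong_paired_test(self.B6, self.A6, self.LABELS6)
        assert fwd.z == pytest.approx(-rev.z)
        assert fwd.p == pytest.approx(rev.p)

    def test_variance_against_bootstrap_small_table(self):
        # At n=6 the DeLong and bootstrap variance estimators differ by
        # small-sample bias of order 1/n, so the band here is wide; the
        # n=40 check below pins the asymptotic agreement.
        res = delong_paired_test(self.A6, self.B6, self.LABELS6)
        var_delong = ((res.auc_a - res.auc_b) / res.z) ** 2
        var_boot = bootstrap_auc_diff_variance(self.A6, self.B6, self.LABELS6,
                                               n_boot=100_000, seed=0)
        assert var_delong == pytest.approx(var_boot, rel=0.35)

    def test_variance_against_bootstrap_moderate_table(self):
        rng = np.random.default_rng(100)
        labels = np.array([1] * 15 + [0] * 25, dtype=bool)
        a = rng.normal(labels * 1.2, 1.0)
        b = 0.6 * a + rng.normal(labels * 0.5, 0.8)
        res = delong_paired_test(a, b, labels)
        var_delong = ((res.auc_a - res.auc_b) / res.z) ** 2
        var_boot = bootstrap_auc_diff_variance(a, b, labels, n_boot=100_000, seed=1)
        assert var_delong == pytest.approx(var_boot, rel=0.10)


class TestOperatingPoint:
    def test_threshold_sweep_example(self):
        scores = [0.9, 0.8, 0.7, 0.6, 0.1, 0.5, 0.4, 0.3, 0.2, 0.65]
        labels = [1, 1, 1, 1, 1, 0, 0, 0, 0, 0]
        op = specificity_at_sensitivity(auc(scores, labels), 0.8)
        assert op.threshold == pytest.approx(0.6)
        assert op.sensitivity == pytest.approx(0.8)
        assert op.specificity == pytest.approx(0.8)

    def test_perfect_separation_specificity_one(self):
        op = specificity_at_sensitivity(
            auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1]), 0.8)
        assert op.specificity == 1.0

    def test_target_zero_gives_strictest_threshold(self):
        op = specificity_at_sensitivity(
            auc([0.1, 0.9, 0.5, 0.7], [0, 1, 0, 1]), 0.0)
        assert op.specificity == 1.0
        assert op.sensitivity == 0.0

    def test_sweep_monotone(self):
        rng = np.random.default_rng(23)
        scores = rng.normal(size=40)
        labels = rng.random(40) < 0.5
        sweep = auc(scores, labels).thresholds
        order = np.argsort(sweep[:, 0])
        assert np.all(np.diff(sweep[order, 1]) <= 1e-12)   # sensitivity falls
        assert np.all(np.diff(sweep[order, 2]) >= -1e-12)  # specificity rises


class TestTableStatistics:
    def test_chi_square_examples(self):
        # second-cohort sex: 17/42 delirious vs 79/164 control female
        assert chi_square_2x2(17, 25, 79, 85) == pytest.approx(0.80, abs=0.005)
        # second-cohort race: 37/42 vs 154/164 white
        assert chi_square_2x2(37, 5, 154, 10) == pytest.approx(1.67, abs=0.005)

    def test_proportional_table_is_zero(self):
        assert chi_square_2x2(10, 10, 20, 20) == pytest.approx(0.0, abs=1e-12)

    def test_invariance_under_transpose_and_swaps(self):
        base = chi_square_2x2(17, 25, 79, 85)
        assert chi_square_2x2(17, 79, 25, 85) == pytest.approx(base)  # transpose
        assert chi_square_2x2(85, 79, 25, 17) == pytest.approx(base)  # both swapped

    def test_zero_margin_rejected(self):
        with pytest.raises(DegenerateTableError):
            chi_square_2x2(0, 0, 5, 5)

    def test_t_from_summaries_age_example(self):
        assert abs(two_sample_t(78.0, 8.0, 42, 69.1, 9.4, 164)) == pytest.approx(5.6, abs=0.1)

    def test_equal_means_zero(self):
        assert two_sample_t(5.0, 1.0, 10, 5.0, 2.0, 12) == 0.0

    def test_t_matches_raw_sample_computation(self):
        from scipy import stats
        rng = np.random.default_rng(29)
        a = rng.normal(1.0, 2.0, size=30)
        b = rng.normal(0.2, 1.5, size=40)
        expected, _ = stats.ttest_ind(a, b, equal_var=True)
        got = two_sample_t(a.mean(), a.std(ddof=1), 30, b.mean(), b.std(ddof=1), 40)
        assert got == pytest.approx(expected)

    def test_invalid_n_rejected(self):
        with pytest.raises(ValueError):
            two_sample_t(1.0, 1.0, 1, 0.0, 1.0, 10)


class TestWilson:
    def test_contains_point_estimate(self):
        lo, hi = wilson_interval(48, 100)
        assert lo < 0.48 < hi

    def test_extremes_stay_in_unit_interval(self):
        lo, hi = wilson_interval(0, 20)
        assert lo == 0.0 and 0 < hi < 0.2
        lo, hi = wilson_interval(20, 20)
        assert 0.8 < lo < 1 and hi == 1.0
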