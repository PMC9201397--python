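import math

import numpy as np
import pytest

from bodyagree import (
    Measure,
    PairedSeries,
    Stratum,
    accuracy_classification,
    bias_summary,
    bland_altman,
    mean_absolute_error,
    paired_series,
    sex_interaction_test,
    summarize_agreement,
)
from bodyagree.errors import DegenerateRegressionError, InsufficientDataError

from conftest import build_cohort


def series_from(ref, cand, measure=Measure.ALM, stratum=Stratum.ALL):
    ref = np.asarray(ref, float)
    cand = np.asarray(cand, float)
    return PairedSeries(
        measure=measure,
        stratum=stratum,
        reference=ref,
        candidate=cand,
        subject_ids=tuple(f"S{i}" for i in range(len(ref))),
    )


def series_from_means_diffs(means, diffs):
    means = np.asarray(means, float)
    diffs = np.asarray(diffs, float)
    return series_from(means - diffs / 2.0, means + diffs / 2.0)


class TestPairedSeries:
    def test_index_measure_divides_by_height_squared(self):
        cohort = build_cohort(female_pairs=[(20.0, 19.0), (18.0, 18.0)], height=1.70)
        s = paired_series(cohort, Measure.ALMI, Stratum.FEMALE)
        assert s.reference[0] == pytest.approx(20.0 / 1.70**2)
        # hand value: 20.0 / 2.89 = 6.920...
        assert s.reference[0] == pytest.approx(6.920, abs=5e-4)

    def test_unit_height_index_equals_mass(self):
        cohort = build_cohort(female_pairs=[(20.0, 19.0), (18.0, 18.0)], height=1.0)
        s_mass = paired_series(cohort, Measure.ALM, Stratum.FEMALE)
        s_idx = paired_series(cohort, Measure.ALMI, Stratum.FEMALE)
        np.testing.assert_array_equal(s_mass.reference, s_idx.reference)

    def test_stratum_vector_length(self, default_cohort):
        s = paired_series(default_cohort, Measure.ALM, Stratum.MALE)
        assert s.n == default_cohort.n_male

    def test_small_stratum_refused(self):
        cohort = build_cohort(male_pairs=[(25, 24)], female_pairs=[(18, 17), (19, 18)])
        with pytest.raises(InsufficientDataError):
            paired_series(cohort, Measure.ALM, Stratum.MALE)

    def test_ffm_fields_used_for_ffm(self):
        cohort = build_cohort(female_pairs=[(18.0, 17.0), (19.0, 18.0)], ffm_offset=25.0)
        s = paired_series(cohort, Measure.FFM, Stratum.ALL)
        assert s.reference[0] == pytest.approx(43.0)


class TestBiasSummary:
    def test_hand_computed_three_pairs(self):
        s = series_from([20, 18, 22], [19, 18.5, 21])
        bias_mean, bias_sd, pct_mean, pct_sd = bias_summary(s)
        assert bias_mean == pytest.approx(-0.5)
        assert bias_sd == pytest.approx(0.8660, abs=1e-4)

    def test_identical_vectors_zero(self):
        s = series_from([20, 18, 22], [20, 18, 22])
        assert bias_summary(s) == (0.0, 0.0, 0.0, 0.0)

    def test_percent_bias_uses_reference_denominator(self):
        s = series_from([20.0, 10.0], [21.0, 9.0])
        _, _, pct_mean, _ = bias_summary(s)
        assert pct_mean == pytest.approx((5.0 + (-10.0)) / 2)


class TestAccuracyClassification:
    def test_boundary_ratio_is_accurate_inclusive(self):
        s = series_from([20.0, 20.0], [19.0, 21.0])  # ratios exactly 0.95 and 1.05
        acc = accuracy_classification(s)
        assert acc.pct_accurate == 100.0

    def test_under_and_over(self):
        s = series_from([20.0, 20.0, 20.0], [18.9, 21.2, 20.0])
        acc = accuracy_classification(s)
        assert acc.pct_under == pytest.approx(100.0 / 3)
        assert acc.pct_over == pytest.approx(100.0 / 3)
        assert acc.pct_accurate == pytest.approx(100.0 / 3)

    def test_partition_sums_to_100(self, default_cohort):
        s = paired_series(default_cohort, Measure.ALM, Stratum.ALL)
        acc = accuracy_classification(s)
        assert acc.pct_accurate + acc.pct_under + acc.pct_over == pytest.approx(100.0)


class TestMeanAbsoluteError:
    def test_hand_computed(self):
        s = series_from_means_diffs([10, 20, 30], [-1.0, 0.5, -1.0])
        assert mean_absolute_error(s) == pytest.approx(2.5 / 3)

    def test_zero_on_identical(self):
        s = series_from([20, 18], [20, 18])
        assert mean_absolute_error(s) == 0.0

    def test_mae_at_least_abs_bias(self, default_cohort):
        s = paired_series(default_cohort, Measure.ALM, Stratum.ALL)
        bias_mean, *_ = bias_summary(s)
        assert mean_absolute_error(s) >= abs(bias_mean)


class TestBlandAltman:
    def test_loa_from_printed_style_summary(self):
        # construct a series whose differences have mean -0.60 and SD 1.21
        rng = np.random.default_rng(0)
        d = rng.normal(size=50)
        d = (d - d.mean()) / d.std(ddof=1) * 1.21 + (-0.60)
        s = series_from_means_diffs(rng.uniform(15, 25, 50), d)
        ba = bland_altman(s)
        assert round(ba.loa_low, 1) == -3.0
        assert round(ba.loa_high, 1) == 1.8

    def test_zero_sd_collapses_to_bias(self):
        s = series_from([10.0, 20.0, 30.0], [9.5, 19.5, 29.5])
        ba = bland_altman(s)
        assert ba.loa_low == ba.loa_high == pytest.approx(-0.5)

    def test_closed_form_three_point_regression(self):
        s = series_from_means_diffs([10.0, 20.0, 30.0], [1.0, 2.0, 3.0])
        ba = bland_altman(s)
        assert ba.prop_bias.slope == pytest.approx(0.1)
        assert ba.prop_bias.intercept == pytest.approx(0.0, abs=1e-12)
        assert ba.prop_bias.r_squared == pytest.approx(1.0)

    def test_loa_width_is_392_sd(self, default_cohort):
        s = paired_series(default_cohort, Measure.FFM, Stratum.ALL)
        _, bias_sd, _, _ = bias_summary(s)
        ba = bland_altman(s)
        assert ba.loa_high - ba.loa_low == pytest.approx(3.92 * bias_sd)

    def test_degenerate_means_axis(self):
        s = series_from([10.0, 9.0, 11.0], [10.0, 11.0, 9.0])  # means all 10
        with pytest.raises(DegenerateRegressionError):
            bland_altman(s)

    def test_needs_three_subjects(self):
        s = series_from([10.0, 20.0], [11.0, 19.0])
        with pytest.raises(InsufficientDataError):
            bland_altman(s)

    def test_significance_flag_matches_p(self, default_cohort):
        s = paired_series(default_cohort, Measure.ALM, Stratum.FEMALE)
        pb = bland_altman(s).prop_bias
        assert pb.significant == (pb.p_value < 0.05)


class TestSexInteraction:
    def test_parallel_shift_gives_null(self):
        # parallel shift: same candidate->reference slope in both sexes
        rng = np.random.default_rng(4)
        male = [(25.0 + x + 5.0 + rng.normal(0, 0.5), 25.0 + x) for x in rng.uniform(-3, 3, 200)]
        female = [(18.0 + x + rng.normal(0, 0.5), 18.0 + x) for x in rng.uniform(-3, 3, 200)]
        cohort = build_cohort(male_pairs=male, female_pairs=female)
        res = sex_interaction_test(cohort, Measure.ALM)
        assert not res.stratify
        # interaction coefficient itself is near zero (independent direct fit)
        import statsmodels.api as sm

        ref = np.array([p[0] for p in male] + [p[0] for p in female])
        cand = np.array([p[1] for p in male] + [p[1] for p in female])
        is_male = np.array([1.0] * len(male) + [0.0] * len(female))
        fit = sm.OLS(ref, sm.add_constant(np.column_stack([cand, is_male, cand * is_male]))).fit()
        assert abs(fit.params[3]) < 0.1

    def test_differing_slopes_detected(self):
        rng = np.random.default_rng(2)
        xm = rng.uniform(20, 30, 100)
        xf = rng.uniform(14, 24, 100)
        male = [(x + rng.normal(0, 0.05), x) for x in xm]          # ref = cand
        female = [(0.5 * x + 9 + rng.normal(0, 0.05), x) for x in xf]  # ref = 0.5 cand + 9
        cohort = build_cohort(male_pairs=male, female_pairs=female)
        res = sex_interaction_test(cohort, Measure.ALM)
        assert res.stratify
        assert res.p_value < 0.01

    def test_single_sex_cohort_refused(self):
        cohort = build_cohort(female_pairs=[(18, 17)] * 10)
        with pytest.raises(InsufficientDataError):
            sex_interaction_test(cohort, Measure.ALM)


class TestSummarize:
    def test_summary_internally_consistent(self, default_cohort):
        s = paired_series(default_cohort, Measure.ALM, Stratum.ALL)
        summary = summarize_agreement(s)
        assert summary.loa_low == pytest.approx(summary.bias_mean - 1.96 * summary.bias_sd)
        assert summary.loa_high == pytest.approx(summary.bias_mean + 1.96 * summary.bias_sd)
        assert summary.mae >= abs(summary.bias_mean)
        assert 0.0 <= summary.prop_bias.r_squared <= 1.0

    def test_percent_bias_rows_identical_for_mass_and_index(self, default_cohort):
        s_mass = summarize_agreement(paired_series(default_cohort, Measure.ALM, Stratum.ALL))
        s_idx = summarize_agreement(paired_series(default_cohort, Measure.ALMI, Stratum.ALL))
        assert s_idx.bias_pct_mean == pytest.approx(s_mass.bias_pct_mean, abs=1e-10)
        assert s_idx.bias_pct_sd == pytest.approx(s_mass.bias_pct_sd, abs=1e-10)
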