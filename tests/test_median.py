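import numpy as np
import pytest

from studbooklife import (Exposure, estimate_mle, fit_survival, median_ci,
                          median_from_curve, quality_tests, to_years,
                          z_statistic)

from conftest import random_cohort


class TestMedian:
    def test_exact_half_returns_that_age(self, two_individual_exposures):
        curve, table = fit_survival(two_individual_exposures)
        assert median_from_curve(curve, table) == 500.0

    def test_interpolated_median(self, four_individual_exposures):
        # x0=400 (L0=0.75), x1=700 (L1=0.375):
        # 400 + 0.25 * 300 / 0.375 = 600
        curve, table = fit_survival(four_individual_exposures)
        assert median_from_curve(curve, table) == pytest.approx(600.0)

    def test_interpolation_ignores_censoring_only_ages(
            self, four_individual_exposures):
        # the censoring at 500 repeats L=0.75 but is not an anchor
        curve, table = fit_survival(four_individual_exposures)
        assert median_from_curve(curve, table) != pytest.approx(
            500 + 0.25 * 200 / 0.375)

    def test_undefined_when_curve_stays_above_half(self):
        exposures = [Exposure(str(i), "male", 365, 500 + i, i == 0)
                     for i in range(10)]  # one death in ten -> L = 0.9
        curve, table = fit_survival(exposures)
        assert median_from_curve(curve, table) is None

    def test_agrees_with_lifelines_within_one_event_age(self):
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(7)
        for _ in range(100):
            exposures = random_cohort(rng, int(rng.integers(10, 51)))
            curve, table = fit_survival(exposures)
            ours = median_from_curve(curve, table)
            kmf = KaplanMeierFitter().fit(
                [e.exit_age for e in exposures],
                [e.event for e in exposures],
                entry=[e.entry_age for e in exposures])
            theirs = kmf.median_survival_time_
            death_ages = table.ages[table.deaths > 0].astype(float)
            if ours is None:
                assert np.isinf(theirs)
                continue
            if np.isinf(theirs):
                # lifelines treats a final exact-0.5 plateau as uncrossed;
                # we report the earliest age attaining 0.5
                assert curve.survival.min() >= 0.5
                continue
            ranks = np.searchsorted(death_ages, [ours, theirs])
            assert abs(int(ranks[0]) - int(ranks[1])) <= 1
            if any(abs(s - 0.5) <= 1e-12 for s in curve.survival):
                assert ours <= theirs  # earliest age attaining 0.5


class TestToYears:
    def test_values_and_propagation(self):
        assert to_years(600) == pytest.approx(600 / 365)
        assert to_years(365) == 1.0
        assert to_years(None) is None


class TestZStatistic:
    def test_zero_at_exact_half(self, two_individual_exposures):
        curve, _ = fit_survival(two_individual_exposures)
        assert z_statistic(curve, 0) == pytest.approx(0.0)

    def test_undefined_at_unit_survival(self):
        exposures = [Exposure("a", "male", 365, 500, False),
                     Exposure("b", "male", 365, 600, True)]
        curve, _ = fit_survival(exposures)
        assert curve.survival[0] == 1.0
        assert z_statistic(curve, 0) is None

    def test_undefined_when_variance_unavailable(self):
        curve, _ = fit_survival([Exposure("a", "male", 365, 500, True)])
        assert z_statistic(curve, 0) is None

    def test_direct_evaluation(self, four_individual_exposures):
        curve, _ = fit_survival(four_individual_exposures)
        survival, variance = 0.75, 0.046875
        expected = ((np.log(-np.log(survival)) - np.log(-np.log(0.5)))
                    * survival * np.log(survival) / np.sqrt(variance))
        assert z_statistic(curve, 0) == pytest.approx(expected)


class TestMedianCI:
    def test_matches_lifelines_on_large_synthetic_cohort(self):
        from lifelines import KaplanMeierFitter
        from lifelines.utils import median_survival_times

        rng = np.random.default_rng(11)
        n = 200
        exit_ = 365 + 1 + rng.exponential(1500, n).astype(int)
        censor = rng.random(n) < 0.2
        exposures = [Exposure(str(i), "male", 365, int(exit_[i]),
                              not censor[i]) for i in range(n)]
        curve, table = fit_survival(exposures)
        lcl, ucl = median_ci(curve, table)
        kmf = KaplanMeierFitter().fit([e.exit_age for e in exposures],
                                      [e.event for e in exposures],
                                      entry=[e.entry_age for e in exposures])
        interval = median_survival_times(kmf.confidence_interval_)
        death_ages = table.ages[table.deaths > 0].astype(float)
        for ours, theirs in zip((lcl, ucl), interval.values.ravel()):
            assert ours is not None and np.isfinite(theirs)
            ranks = np.searchsorted(death_ages, [ours, theirs])
            assert abs(int(ranks[0]) - int(ranks[1])) <= 1

    def test_ordered_around_median(self):
        rng = np.random.default_rng(3)
        n = 300
        exit_ = 365 + 1 + rng.exponential(2000, n).astype(int)
        exposures = [Exposure(str(i), "male", 365, int(a), True)
                     for i, a in enumerate(exit_)]
        curve, table = fit_survival(exposures)
        mle = median_from_curve(curve, table)
        lcl, ucl = median_ci(curve, table)
        assert lcl <= mle <= ucl

    def test_undefined_upper_limit_when_boundary_never_crossed(self):
        # heavy censoring right after the median: the +1.96 boundary is
        # never reached on the late side
        exposures = ([Exposure(f"d{i}", "male", 365, 500 + i, True)
                      for i in range(26)]
                     + [Exposure(f"c{i}", "male", 365, 600 + i, False)
                        for i in range(24)])
        curve, table = fit_survival(exposures)
        lcl, ucl = median_ci(curve, table)
        assert ucl is None
        assert lcl is not None

    def test_degenerate_single_death(self):
        curve, table = fit_survival([Exposure("a", "male", 365, 500, True)])
        assert median_ci(curve, table) == (None, None)


class TestQualityTests:
    def base(self, **overrides):
        values = dict(mle_days=2000.0, lcl_days=1500.0, ucl_days=2500.0,
                      n_start=100, n_at_median=50, max_longevity=10000)
        values.update(overrides)
        return quality_tests(**values)

    def test_all_pass_on_strong_data(self):
        assert self.base().all_pass()

    def test_undefined_median_fails_first_test(self):
        tests = self.base(mle_days=None)
        assert not tests.calculable

    def test_first_class_threshold_is_strict(self):
        assert not self.base(n_start=30).first_class_n
        assert self.base(n_start=31).first_class_n

    def test_median_risk_threshold_is_strict(self):
        assert not self.base(n_at_median=20).median_n
        assert self.base(n_at_median=21).median_n

    def test_ci_defined(self):
        assert not self.base(ucl_days=None).ci_defined

    def test_ci_precision_threshold(self):
        assert not self.base(lcl_days=0.0, ucl_days=0.34 * 10000).ci_precise
        assert self.base(lcl_days=0.0, ucl_days=0.33 * 10000).ci_precise

    def test_estimate_mle_flags_data_deficient(
            self, four_individual_exposures):
        curve, table = fit_survival(four_individual_exposures)
        result = estimate_mle(curve, table)
        assert result.data_deficient  # four animals: every size test fails
        assert result.mle_days == pytest.approx(600.0)  # still reported
        assert result.mle_years == pytest.approx(600 / 365)
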