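"""Accuracy-profile statistics: variance components, trueness, tolerance
intervals, total error and the uncertainty budget."""

import math

import numpy as np
import pytest
from scipy import stats

from patvis.datasets import load_validation_summary
from patvis.validation import (ATPSpec, LevelData, VarianceComponents,
                               absolute_total_error, build_accuracy_profile,
                               check_atp, profile_rows_from_summary,
                               relative_total_error, round_half_away,
                               tolerance_limits, total_error, trueness,
                               uncertainty, variance_components)


def level_from_sim(rng, true_conc, p, n, sigma_r, sigma_B, bias=0.0):
    day = rng.normal(0.0, sigma_B, size=(p, 1))
    eps = rng.normal(0.0, sigma_r, size=(p, n))
    return LevelData(true_conc=true_conc,
                     predictions=true_conc * (1 + bias / 100.0) + day + eps)


class TestVarianceComponents:
    def test_identical_predictions_give_zero(self):
        level = LevelData(true_conc=10.0, predictions=np.full((3, 4), 10.2))
        vc = variance_components(level)
        assert (vc.s2_r, vc.s2_B, vc.s2_IP) == (0.0, 0.0, 0.0)

    def test_hand_computed_two_by_two(self):
        # day A = (1, 3), day B = (5, 7): MS_within = 2, MS_between = 16
        level = LevelData(true_conc=5.0,
                          predictions=np.array([[1.0, 3.0], [5.0, 7.0]]))
        vc = variance_components(level)
        assert vc.s2_r == pytest.approx(2.0)
        assert vc.s2_B == pytest.approx(7.0)
        assert vc.s2_IP == pytest.approx(9.0)

    def test_negative_moment_estimate_clipped(self, rng):
        # no day effect at all: between-day MS often below within MS
        level = LevelData(true_conc=10.0,
                          predictions=np.array([[9.9, 10.1, 10.0, 10.2],
                                                [10.05, 9.95, 10.1, 9.95]]))
        vc = variance_components(level)
        assert vc.s2_B >= 0.0
        assert vc.s2_IP >= vc.s2_r

    def test_estimator_consistency_monte_carlo(self):
        # 1000 simulated designs, p=2, n=50, sigma_r=0.10, sigma_B=0.05:
        # the mean repeatability estimate recovers sigma_r^2 = 0.01
        rng = np.random.default_rng(42)
        est_r, est_B = [], []
        for _ in range(1000):
            level = level_from_sim(rng, 14.45, p=2, n=50,
                                   sigma_r=0.10, sigma_B=0.05)
            vc = variance_components(level)
            est_r.append(vc.s2_r)
            est_B.append(vc.s2_B)
        assert np.mean(est_r) == pytest.approx(0.01, rel=0.02)
        # clipping inflates the between-day mean slightly; stay within 15%
        assert np.mean(est_B) == pytest.approx(0.0025, rel=0.15)

    def test_single_series_rejected(self):
        with pytest.raises(ValueError):
            variance_components(
                LevelData(true_conc=1.0, predictions=np.ones((1, 5))))


class TestTrueness:
    def test_published_row_13_45(self):
        # the published row prints bias 0.47 / recovery 100.47 from
        # unrounded means; recomputation from the 2-dp means lands within
        # rounding of it, and recovery - bias = 100 holds exactly
        level = LevelData(true_conc=13.45, predictions=np.full((2, 2), 13.51))
        bias, recovery = trueness(level)
        assert bias == pytest.approx(0.47, abs=0.03)
        assert recovery - bias == pytest.approx(100.0)

    def test_doe_row_14_45(self):
        level = LevelData(true_conc=14.45, predictions=np.full((2, 2), 14.82))
        bias, _ = trueness(level)
        assert round_half_away(bias) == 2.56

    def test_exact_prediction_is_unbiased(self):
        level = LevelData(true_conc=12.0, predictions=np.full((2, 3), 12.0))
        bias, recovery = trueness(level)
        assert bias == 0.0
        assert recovery == 100.0


class TestToleranceLimits:
    def test_zero_variance_degenerates_to_bias(self):
        level = LevelData(true_conc=10.0, predictions=np.full((2, 5), 10.3))
        lo, hi = tolerance_limits(level)
        assert lo == hi == pytest.approx(3.0)

    def test_asymptotic_z_limit(self):
        # with known components and p*n -> infinity the half-width tends
        # to z_{0.975} * RSD_IP
        vc = VarianceComponents(s2_r=0.01, s2_B=0.01)
        p, n = 2000, 5000
        level = LevelData(true_conc=10.0,
                          predictions=np.full((p, n), 10.0))
        lo, hi = tolerance_limits(level, vc=vc)
        half = (hi - lo) / 2
        rsd_ip = 100.0 * math.sqrt(vc.s2_IP) / 10.0
        z = stats.norm.ppf(0.975)
        assert half == pytest.approx(z * rsd_ip, rel=0.01)

    def test_interval_contains_bias(self, rng):
        for _ in range(10):
            level = level_from_sim(rng, 13.45, 2, 50, 0.08, 0.08, bias=1.0)
            lo, hi = tolerance_limits(level)
            bias, _ = trueness(level)
            assert lo <= bias <= hi

    def test_widens_with_beta(self, rng):
        level = level_from_sim(rng, 13.45, 2, 50, 0.08, 0.08)
        w80 = np.diff(tolerance_limits(level, beta=0.80))[0]
        w95 = np.diff(tolerance_limits(level, beta=0.95))[0]
        w99 = np.diff(tolerance_limits(level, beta=0.99))[0]
        assert w80 < w95 < w99

    def test_pure_between_day_variance_limit(self):
        # s2_r = 0 forces the R = infinity branch: df = p - 1
        vc = VarianceComponents(s2_r=0.0, s2_B=0.04)
        level = LevelData(true_conc=10.0, predictions=np.full((3, 10), 10.0))
        lo, hi = tolerance_limits(level, vc=vc)
        t_q = stats.t.ppf(0.975, 2)
        widen = math.sqrt(1.0 + 1.0 / (3 * 10 * (1.0 / 10)))
        want = t_q * widen * 100.0 * 0.2 / 10.0
        assert (hi - lo) / 2 == pytest.approx(want, rel=1e-12)

    def test_known_component_coverage_is_nominal(self, rng):
        # with components known exactly, z-based limits cover 95% of
        # future observations around the estimated mean
        sigma_r, sigma_B, p, n = 0.10, 0.05, 2, 50
        s2_ip = sigma_r ** 2 + sigma_B ** 2
        var_mean = sigma_B ** 2 / p + sigma_r ** 2 / (p * n)
        half = stats.norm.ppf(0.975) * math.sqrt(s2_ip + var_mean)
        trials = 100_000
        mean_err = rng.normal(0, math.sqrt(var_mean), trials)
        future = rng.normal(0, math.sqrt(s2_ip), trials)
        covered = np.abs(future - mean_err) <= half
        assert covered.mean() == pytest.approx(0.95, abs=0.01)


class TestTotalErrorAndUncertainty:
    summary = load_validation_summary()

    def test_relative_total_error_reproduces_summary(self):
        want = [0.96, 1.42, 1.34, 1.23]
        got = [round_half_away(relative_total_error(r.relative_bias_pct,
                                                    r.rsd_ip_pct))
               for r in self.summary.itertuples()]
        assert got == want

    def test_absolute_total_error_level_15_45(self):
        got = absolute_total_error(15.45, 15.40, 1.05)
        assert round_half_away(got) == 0.21

    def test_uncertainty_budget_reconciles_printed_row(self):
        # back-substitution from the level-11.66 published summary
        s_r = 0.55 / 100 * 11.65
        s_ip = 0.84 / 100 * 11.65
        vc = VarianceComponents(s2_r=s_r ** 2, s2_B=s_ip ** 2 - s_r ** 2)
        level = LevelData(true_conc=11.66, predictions=np.full((2, 50), 11.65))
        u_bias, u_y, u_exp = uncertainty(level, vc=vc)
        assert round_half_away(u_bias) == 0.05
        assert round_half_away(u_y) == 0.11
        assert round_half_away(u_exp) == 0.22

    def test_expanded_uncertainty_is_twice_u(self, rng):
        level = level_from_sim(rng, 13.45, 2, 50, 0.08, 0.05)
        _, u_y, u_exp = uncertainty(level)
        assert u_exp == pytest.approx(2.0 * u_y)

    def test_zero_variance_gives_zero_uncertainty(self):
        level = LevelData(true_conc=10.0, predictions=np.full((2, 5), 10.0))
        assert uncertainty(level) == (0.0, 0.0, 0.0)

    def test_total_error_combines_bias_and_precision(self, rng):
        level = level_from_sim(rng, 13.45, 2, 50, 0.08, 0.05, bias=1.0)
        vc = variance_components(level)
        abs_err, rel_err = total_error(level, vc)
        bias, _ = trueness(level)
        assert rel_err == pytest.approx(
            abs(bias) + 100 * math.sqrt(vc.s2_IP) / level.mean_predicted)
        assert abs_err >= abs(level.mean_predicted - level.true_conc)


class TestAccuracyProfile:
    def make_levels(self, rng, bias=0.0):
        return [level_from_sim(rng, c, 2, 50, 0.006 * c, 0.004 * c, bias=bias)
                for c in (11.66, 13.45, 15.45, 17.50)]

    def test_clean_data_passes_atp(self, rng):
        profile = build_accuracy_profile(self.make_levels(rng))
        assert profile.passes
        assert profile.loq == 11.66
        for row in profile.rows:
            assert row.recovery - row.relative_bias == pytest.approx(100.0)
            assert row.tolerance_low <= row.relative_bias <= row.tolerance_high

    def test_six_percent_bias_fails(self, rng):
        levels = self.make_levels(rng)
        levels[1] = level_from_sim(rng, 13.45, 2, 50, 0.08, 0.05, bias=6.0)
        profile = build_accuracy_profile(levels)
        assert not profile.passes
        bad = [r for r in profile.rows if r.level == 13.45][0]
        assert not bad.within_acceptance
        assert profile.loq == 11.66  # lowest level still passes

    def test_published_summary_round_trip(self):
        rows = profile_rows_from_summary(load_validation_summary())
        for row, want in zip(rows, [0.96, 1.42, 1.34, 1.23]):
            assert round_half_away(row.rel_total_error) == want
            assert row.recovery - row.relative_bias == pytest.approx(100.0)
        assert all(r.within_acceptance for r in rows)

    def test_check_atp_on_published_summary(self):
        rows = profile_rows_from_summary(load_validation_summary())
        report = check_atp(rows)
        assert report.max_rsd_IP == pytest.approx(1.09)
        assert report.max_rsd_repeatability == pytest.approx(0.80)
        assert report.max_abs_bias == pytest.approx(0.47)
        assert report.passes

    def test_check_atp_flags_high_rsd(self):
        rows = profile_rows_from_summary(load_validation_summary())
        rows[2].rsd_IP = 2.0
        report = check_atp(rows, ATPSpec())
        assert not report.rsd_ok
        assert rows[2].level in report.offending_levels

    def test_two_levels_required(self, rng):
        with pytest.raises(ValueError):
            build_accuracy_profile(self.make_levels(rng)[:1])
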