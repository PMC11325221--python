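"""Activity conversion, residual series, censoring, and first-order fits."""

import math

import numpy as np
import pytest

from desqspr import kinetics as kin
from desqspr import synthetic_data as syn


class TestActivityFromSlope:
    @pytest.mark.parametrize(
        "slope, expected",
        [
            (0.0, 0.0),
            # chosen so that slope·10⁶/(6220·0.61) = 1.0000
            (0.0037942, 1.0000),
            (0.00622, 1.639),
        ],
    )
    def test_plate_reader_conversion(self, slope, expected):
        assay = kin.ActivityAssay(slope=slope)
        assert kin.activity_from_slope(assay) == pytest.approx(expected, abs=5e-4)

    def test_invalid_constants_rejected(self):
        with pytest.raises(ValueError):
            kin.ActivityAssay(slope=0.1, epsilon=0.0)
        with pytest.raises(ValueError):
            kin.ActivityAssay(slope=0.1, path_length=-1.0)


class TestResidualSeries:
    def test_constant_activity_gives_all_100(self):
        series = kin.residual_series([(1.0, 2.0), (2.0, 2.0)], t0_activity=2.0)
        assert series.residual == pytest.approx([100.0, 100.0, 100.0])

    def test_half_activity_gives_50(self):
        series = kin.residual_series([(7.0, 1.0)], t0_activity=2.0)
        assert series.residual[-1] == pytest.approx(50.0)

    def test_matches_brute_force_percentages(self):
        rng = np.random.default_rng(5)
        t0 = 3.7
        raw = [(float(t), float(a)) for t, a in
               zip(np.arange(1, 9), rng.uniform(0.1, 5.0, 8))]
        series = kin.residual_series(raw, t0)
        expected = [100.0] + [100.0 * a / t0 for _, a in raw]
        assert series.residual == pytest.approx(expected)

    def test_nonpositive_t0_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            kin.residual_series([(1.0, 1.0)], t0_activity=0.0)


class TestCensorSeries:
    # the reference-buffer stability course of the stable (S)-selective
    # alcohol dehydrogenase: transient overshoot above 100% for ~2 weeks
    ADH_A_TIMES = [0, 0.1, 1, 2, 3, 4, 7, 14, 21]
    ADH_A_RESIDUALS = [100, 112, 120, 138, 138, 133, 126, 62, 50]

    def test_overshoot_course_retains_day_0_14_21(self):
        series = kin.ActivityTimeSeries(
            times=np.array(self.ADH_A_TIMES, dtype=float),
            residual=np.array(self.ADH_A_RESIDUALS, dtype=float),
            label="ADH-A buffer",
        )
        censored = kin.censor_series(series, "drop_over_100")
        assert censored.times.tolist() == [0.0, 14.0, 21.0]
        assert censored.residual.tolist() == [100.0, 62.0, 50.0]
        assert censored.censored_n == 6

    def test_series_within_100_unchanged(self):
        series = kin.ActivityTimeSeries(
            times=np.array([0.0, 1.0, 2.0]),
            residual=np.array([100.0, 80.0, 60.0]),
        )
        censored = kin.censor_series(series)
        assert np.array_equal(censored.residual, series.residual)
        assert censored.censored_n == 0

    def test_matches_brute_force_filter(self):
        rng = np.random.default_rng(11)
        times = np.arange(15, dtype=float)
        residual = np.concatenate([[100.0], rng.uniform(20, 180, 14)])
        series = kin.ActivityTimeSeries(times=times, residual=residual)
        censored = kin.censor_series(series)
        keep = [(t, r) for t, r in zip(times, residual) if r <= 100.0]
        assert censored.times.tolist() == [t for t, _ in keep]
        assert censored.residual.tolist() == [r for _, r in keep]

    def test_keep_all_policy_is_identity(self):
        series = kin.ActivityTimeSeries(
            times=np.array([0.0, 1.0]), residual=np.array([100.0, 130.0])
        )
        assert kin.censor_series(series, "keep_all") is series


class TestFitFirstOrder:
    @staticmethod
    def exponential_series(k_day, a0=100.0, times=None):
        t = np.array(times if times is not None else np.arange(0.0, 11.0))
        return kin.ActivityTimeSeries(times=t, residual=a0 * np.exp(-k_day * t))

    def test_noiseless_recovery_to_1e8(self):
        fit = kin.fit_first_order(self.exponential_series(0.1))
        assert fit.k_per_day == pytest.approx(0.1, rel=1e-8)
        assert fit.A_R0 == pytest.approx(100.0, rel=1e-8)
        assert fit.k_per_h == pytest.approx(0.1 / 24.0, rel=1e-8)

    def test_flat_series_gives_infinite_half_life(self):
        fit = kin.fit_first_order(self.exponential_series(0.0))
        assert fit.k_per_day == 0.0
        assert math.isinf(fit.t_half_days)
        assert "no_decay" in fit.flags

    def test_scale_equivariance(self):
        series = self.exponential_series(0.3)
        scaled = kin.ActivityTimeSeries(times=series.times,
                                        residual=series.residual * 3.5)
        f1, f2 = kin.fit_first_order(series), kin.fit_first_order(scaled)
        assert f2.k_per_day == pytest.approx(f1.k_per_day, rel=1e-8)
        assert f2.A_R0 == pytest.approx(3.5 * f1.A_R0, rel=1e-8)

    def test_time_unit_equivariance(self):
        """Times in hours instead of days scale k̂ by exactly 24."""
        series_days = self.exponential_series(0.3)
        series_hours = kin.ActivityTimeSeries(times=series_days.times * 24.0,
                                              residual=series_days.residual)
        f_days = kin.fit_first_order(series_days)
        f_hours = kin.fit_first_order(series_hours)
        assert f_hours.k_per_day == pytest.approx(f_days.k_per_day / 24.0,
                                                  rel=1e-7)

    def test_dead_from_second_point_gets_fast_sentinel(self):
        series = kin.ActivityTimeSeries(
            times=np.array([0.0, 1.0, 2.0, 3.0]),
            residual=np.array([100.0, 0.0, 0.0, 0.0]),
        )
        fit = kin.fit_first_order(series)
        assert fit.k_per_h == kin.K_FAST_SENTINEL_PER_H
        assert "faster_than_resolvable" in fit.flags

    def test_trailing_zeros_are_retained_in_fit(self):
        t = np.arange(0.0, 8.0)
        r = 100.0 * np.exp(-2.0 * t)
        r[4:] = 0.0  # below detection
        fit = kin.fit_first_order(kin.ActivityTimeSeries(times=t, residual=r))
        assert fit.k_per_day > 1.5  # still recognizes fast decay

    def test_fixed_intercept_needs_two_points(self):
        series = kin.ActivityTimeSeries(times=np.array([0.0, 2.0]),
                                        residual=np.array([100.0, 25.0]))
        fit = kin.fit_first_order(series, fix_intercept=True)
        # 100·e^(−2k) = 25 → k = ln(4)/2
        assert fit.k_per_day == pytest.approx(math.log(4.0) / 2.0, rel=1e-8)
        with pytest.raises(kin.FitError):
            kin.fit_first_order(series, fix_intercept=False)

    def test_noisy_recovery_is_nearly_unbiased(self):
        """Small-noise simulated screens recover k with ~1% median error."""
        rng = np.random.default_rng(2)
        spec = syn.SyntheticSpec(overshoot_prob=0.0)
        errors = []
        for _ in range(50):
            k = float(np.exp(rng.uniform(np.log(0.05), np.log(2.0))))
            series = syn.synth_decay_series(
                k, spec, seed=int(rng.integers(2**31 - 1))
            )
            fit = kin.fit_first_order(series)
            errors.append(abs(fit.k_per_day - k) / k)
        assert np.median(errors) < 0.02


class TestHalfLife:
    def test_printed_slow_rate_gives_36_1_days(self):
        # the most stabilizing betaine/ethylene-glycol formulation
        assert kin.half_life(0.0008, unit="per_h") == pytest.approx(36.1, abs=0.05)

    def test_printed_half_life_inverts_to_rate(self):
        # glucose dehydrogenase in its best glycerol-based solvent
        k_per_h = math.log(2) / 12.7 / 24.0
        assert k_per_h == pytest.approx(0.0023, abs=5e-5)
        assert kin.half_life(k_per_h, unit="per_h") == pytest.approx(12.7, rel=1e-9)

    def test_ln2_per_day_is_one_day(self):
        assert kin.half_life(math.log(2), unit="per_day") == pytest.approx(1.0)

    def test_zero_rate_is_infinite(self):
        assert math.isinf(kin.half_life(0.0))

    def test_fit_object_input(self):
        series = TestFitFirstOrder.exponential_series(0.2)
        fit = kin.fit_first_order(series)
        assert kin.half_life(fit) == pytest.approx(math.log(2) / 0.2, rel=1e-6)
        # the invariant k·t½ = ln 2 in consistent units
        assert fit.k_per_day * fit.t_half_days == pytest.approx(math.log(2))
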