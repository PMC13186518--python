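"""Cosinor fitting and nonparametric rest-activity metrics."""

import numpy as np
import pytest

from actiphen.circadian_features import (
    circadian_rhythm_strength,
    fit_cosinor,
    interdaily_stability,
    intradaily_variability,
    nonparametric_day_features,
)


def sinusoid(t, mesor=50.0, amp=30.0, peak=15.0, period=24.0):
    return mesor + amp * np.cos(2 * np.pi * (t - peak) / period)


def grid_search_cosinor(t, y, period=24.0):
    """Brute-force oracle: best (M, A, t_peak) over a dense grid by SSE."""
    mesors = np.linspace(y.min(), y.max(), 41)
    amps = np.linspace(0, (y.max() - y.min()), 41)
    peaks = np.linspace(0, period, 97, endpoint=False)
    best = (np.inf, None)
    cosses = np.cos(2 * np.pi * (t[None, :] - peaks[:, None]) / period)
    for m in mesors:
        for a in amps:
            sse = np.sum((y[None, :] - (m + a * cosses)) ** 2, axis=1)
            j = int(np.argmin(sse))
            if sse[j] < best[0]:
                best = (sse[j], (m, a, peaks[j]))
    return best[1]


class TestFitCosinor:
    def test_noiseless_sinusoid_recovered_exactly(self):
        t = np.arange(0, 24, 0.5)
        fit = fit_cosinor(t, sinusoid(t))
        assert fit.mesor == pytest.approx(50.0)
        assert fit.amplitude == pytest.approx(30.0)
        assert fit.acrophase_time == pytest.approx(15.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_constant_counts_degenerate(self):
        t = np.arange(0, 24, 1.0)
        fit = fit_cosinor(t, np.full_like(t, 7.0))
        assert fit.mesor == pytest.approx(7.0)
        assert fit.amplitude == pytest.approx(0.0, abs=1e-9)
        assert fit.r_squared == 0.0

    def test_all_times_equal_rejected(self):
        with pytest.raises(ValueError):
            fit_cosinor(np.full(10, 3.0), np.arange(10.0))

    def test_matches_grid_search_on_random_instances(self, rng):
        """Least-squares solution equals the brute-force grid optimum within
        grid resolution on 50 random small instances."""
        for _ in range(50):
            t = np.sort(rng.uniform(0, 24, size=24))
            y = sinusoid(t, rng.uniform(20, 80), rng.uniform(5, 40),
                         rng.uniform(0, 24)) + rng.normal(0, 5, size=24)
            fit = fit_cosinor(t, y)
            gm, ga, gp = grid_search_cosinor(t, y)
            assert fit.mesor == pytest.approx(gm, abs=2.0)
            assert fit.amplitude == pytest.approx(ga, abs=2.0)
            dphase = min(abs(fit.acrophase_time - gp),
                         24 - abs(fit.acrophase_time - gp))
            assert dphase <= 0.5  # two grid steps

    def test_noisy_recovery_within_three_standard_errors(self, rng):
        t = np.arange(0, 24, 24 / 2880)
        sigma = 5.0
        y = sinusoid(t) + rng.normal(0, sigma, size=t.size)
        fit = fit_cosinor(t, y)
        se_amp = sigma * np.sqrt(2 / t.size)
        assert abs(fit.mesor - 50.0) <= 3 * sigma / np.sqrt(t.size)
        assert abs(fit.amplitude - 30.0) <= 3 * se_amp
        assert abs(fit.acrophase_time - 15.0) <= 3 * se_amp / 30.0 * (24 / (2 * np.pi))

    def test_phase_shift_moves_acrophase(self):
        t = np.arange(0, 24, 0.25)
        base = fit_cosinor(t, sinusoid(t, peak=23.0))
        shifted = fit_cosinor(t, sinusoid(t, peak=(23.0 + 2.0) % 24))
        assert shifted.acrophase_time == pytest.approx((base.acrophase_time + 2) % 24)


class TestIntradailyVariability:
    def test_pure_sinusoid_is_smooth(self):
        hours = np.arange(24.0)
        assert intradaily_variability(sinusoid(hours)) <= 0.1

    def test_white_noise_expectation_near_two(self, rng):
        """Mean IV over 2000 Monte-Carlo white-noise days approaches the
        known uncorrelated-noise expectation of 2."""
        ivs = [intradaily_variability(rng.normal(size=24)) for _ in range(2000)]
        assert 1.8 <= np.mean(ivs) <= 2.2

    def test_constant_day_undefined(self):
        assert np.isnan(intradaily_variability(np.full(24, 3.0)))


class TestInterdailyStability:
    def test_identical_days_give_one(self, rng):
        profile = rng.gamma(2.0, 50.0, size=24)
        assert interdaily_stability([profile] * 5) == pytest.approx(1.0)

    def test_white_noise_five_days_near_one_fifth(self, rng):
        """E[IS] for independent noise across d days is ~1/d (Monte Carlo)."""
        vals = [interdaily_stability(list(rng.normal(size=(5, 24))))
                for _ in range(2000)]
        assert np.mean(vals) == pytest.approx(0.2, abs=0.03)

    def test_single_day_missing(self, rng):
        assert np.isnan(interdaily_stability([rng.normal(size=24)]))


class TestNonparametricDayFeatures:
    def _day(self, counts):
        t = np.arange(len(counts)) * (24 / len(counts))
        return nonparametric_day_features(t, np.asarray(counts, float))

    def test_square_wave_boundary(self):
        counts = np.concatenate([np.full(1200, 100.0), np.zeros(1680)])
        f = self._day(counts)
        assert f["m10"] == pytest.approx(100.0)
        assert f["l5"] == pytest.approx(0.0)
        assert f["relative_amplitude"] == pytest.approx(1.0)

    def test_l5_never_exceeds_m10(self, rng):
        f = self._day(rng.gamma(1.5, 80.0, size=2880))
        assert f["l5"] <= f["m10"]

    def test_off_wrist_epochs_excluded_not_zeroed(self):
        counts = np.full(2880, 50.0)
        with_nan = counts.copy()
        with_nan[1000:1100] = np.nan  # off-wrist stretch
        f = self._day(with_nan)
        assert f["mean_activity"] == pytest.approx(50.0)
        assert f["l5"] == pytest.approx(50.0)  # not biased toward zero

    def test_scaling_invariance(self, rng):
        """Scaling counts by c scales location/size features by c and leaves
        the dimensionless metrics unchanged."""
        t = np.arange(2880) * (24 / 2880)
        counts = np.clip(sinusoid(t, 100, 80, 14) + rng.normal(0, 30, 2880), 0, None)
        c = 3.7
        f1 = nonparametric_day_features(t, counts)
        f2 = nonparametric_day_features(t, c * counts)
        for name in ("mean_activity", "sd_activity", "rmssd_activity", "m10", "l5"):
            assert f2[name] == pytest.approx(c * f1[name], rel=1e-9)
        for name in ("intradaily_variability", "relative_amplitude"):
            assert f2[name] == pytest.approx(f1[name], rel=1e-9)
        fit1 = fit_cosinor(t, counts)
        fit2 = fit_cosinor(t, c * counts)
        assert fit2.mesor == pytest.approx(c * fit1.mesor)
        assert fit2.amplitude == pytest.approx(c * fit1.amplitude)
        assert fit2.acrophase_time == pytest.approx(fit1.acrophase_time)
        assert fit2.r_squared == pytest.approx(fit1.r_squared)


class TestCircadianRhythmStrength:
    def test_limits_and_monotonicity(self, rng):
        t = np.arange(2880) * (24 / 2880)
        clean = sinusoid(t)
        assert circadian_rhythm_strength(t, clean) == pytest.approx(1.0)
        noise = rng.normal(0, 30.0, size=t.size)
        assert circadian_rhythm_strength(t, noise + 50.0) <= 0.05
        mid = circadian_rhythm_strength(t, clean + noise)
        assert 0.05 < mid < 1.0
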