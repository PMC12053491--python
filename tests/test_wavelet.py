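"""Wavelet power, red-noise background and rhythm test.

The fast FFT-based transform is checked against an independent direct
O(N^2 S) summation of the defining formula; the background spectrum against
hand-evaluated values; and the rhythm decision against generator ground
truth.
"""

import numpy as np
import pytest
from scipy.stats import chi2

from circascan import (
    DegenerateSeriesError,
    RedNoiseModel,
    SyntheticConfig,
    UniformSeries,
    ValidationError,
    cwt,
    fit_rednoise,
    generate_null_series,
    generate_series,
    preprocess,
    rednoise_power,
    rhythm_test,
    significance_curve,
)
from circascan.wavelet import default_scales, morlet_fourier_factor


def direct_cwt_power(series, scales, omega0=6.0):
    """Independent oracle: direct summation of W_n(s), no FFT."""
    n = series.n
    dt = series.dt_h
    power = np.empty((len(scales), n))
    idx = np.arange(n)
    for j, s in enumerate(scales):
        for t in range(n):
            eta = (idx - t) * dt / s
            psi_conj = np.pi ** -0.25 * np.exp(-1j * omega0 * eta - 0.5 * eta**2)
            w = np.sqrt(dt / s) * np.sum(series.values * psi_conj)
            power[j, t] = np.abs(w) ** 2
    return power


class TestCwt:
    def test_matches_direct_summation_oracle(self, rng):
        values = np.cos(2 * np.pi * np.arange(400) * 0.2 / 24) + 0.3 * rng.normal(size=400)
        s = UniformSeries.from_values(values, dt_h=0.2)
        spec = cwt(s, n_scales=12, s0=0.8)
        oracle = direct_cwt_power(s, spec.scales)
        err = np.abs(spec.power - oracle) / oracle.max()
        assert err.max() < 1e-6

    def test_zero_signal_zero_power(self):
        s = UniformSeries.from_values(np.zeros(256), dt_h=0.5)
        assert np.all(cwt(s).power == 0)

    def test_scale_argmax_at_signal_period(self):
        t = np.arange(2000) * 0.2
        s = UniformSeries(t, np.cos(2 * np.pi * t / 24), dt_h=0.2)
        spec = cwt(s)
        med = np.median(spec.power, axis=1)
        best = spec.periods[np.argmax(med)]
        step = 2**spec.dj
        assert 24 / step <= best <= 24 * step

    def test_power_is_quadratic_in_amplitude(self, rng):
        values = rng.normal(size=300)
        s1 = UniformSeries.from_values(values, dt_h=0.5)
        s2 = UniformSeries.from_values(2 * values, dt_h=0.5)
        p1 = cwt(s1, n_scales=10).power
        p2 = cwt(s2, n_scales=10).power
        np.testing.assert_allclose(p2, 4 * p1, rtol=1e-9)

    def test_periods_increase_with_scales(self, cosine_series):
        spec = cwt(cosine_series)
        assert np.all(np.diff(spec.periods) > 0)
        assert np.all(spec.power >= 0)
        np.testing.assert_allclose(
            spec.periods / spec.scales, morlet_fourier_factor(spec.omega0)
        )

    def test_cross_check_against_pywavelets(self):
        """Independent CWT implementation agrees on the dominant period."""
        pywt = pytest.importorskip("pywt")
        dt = 0.2
        t = np.arange(2000) * dt
        y = np.cos(2 * np.pi * t / 24)
        wavelet = "cmor1.5-1.0"
        scales = np.geomspace(10, 400, 60)
        coeffs, freqs = pywt.cwt(y, scales, wavelet, sampling_period=dt)
        gws = (np.abs(coeffs) ** 2).mean(axis=1)
        pywt_period = 1.0 / freqs[np.argmax(gws)]
        spec = cwt(UniformSeries(t, y, dt_h=dt))
        ours = spec.periods[np.argmax(spec.power.mean(axis=1))]
        assert pywt_period == pytest.approx(24, rel=0.08)
        assert ours == pytest.approx(pywt_period, rel=0.1)


class TestRedNoise:
    def test_white_noise_spectrum_is_flat_unity(self):
        model = RedNoiseModel.from_alpha(0.0, 512)
        np.testing.assert_array_equal(model.spectrum, 1.0)

    def test_hand_evaluated_value_alpha_half_k_zero(self):
        assert rednoise_power(0.5, 1000, 0) == pytest.approx(3.0)

    def test_spectrum_nonincreasing_and_unit_mean(self):
        n = 512
        k_full = np.arange(n)
        pk = rednoise_power(0.6, n, k_full)
        half = rednoise_power(0.6, n, np.arange(n // 2 + 1))
        assert np.all(np.diff(half) <= 1e-12)
        assert pk.mean() == pytest.approx(1.0, abs=1e-6)

    def test_alpha_estimate_on_white_noise(self, rng):
        s = UniformSeries.from_values(rng.normal(size=10_000), dt_h=0.1)
        model = fit_rednoise(s)
        assert model.alpha < 3 / np.sqrt(10_000) + 1e-12

    def test_alpha_estimate_recovers_ar1(self):
        cfg = SyntheticConfig(
            duration_h=(20_000 - 1) / 30, dt_h=1 / 30, trend_coeffs=(0.0,),
            osc_amplitude=0.0, noise_alpha=0.7, noise_sigma=1.0, seed=8,
        )
        model = fit_rednoise(generate_series(cfg))
        assert model.alpha == pytest.approx(0.7, abs=0.05)

    def test_constant_series_degenerate(self):
        with pytest.raises(DegenerateSeriesError):
            fit_rednoise(UniformSeries.from_values(np.full(100, 2.0), dt_h=1.0))


class TestSignificance:
    def test_white_noise_threshold_closed_form(self, cosine_series):
        spec = cwt(cosine_series)
        noise = RedNoiseModel.from_alpha(0.0, cosine_series.n)
        sig = significance_curve(spec, noise, variance=1.0, quantile=0.95)
        expected = 0.5 * (-2.0 * np.log(0.05))  # chi2(2) quantile in closed form
        np.testing.assert_allclose(sig.threshold, expected, rtol=1e-12)

    def test_tiny_quantile_makes_everything_significant(self, cosine_series):
        spec = cwt(cosine_series)
        noise = RedNoiseModel.from_alpha(0.0, cosine_series.n)
        sig = significance_curve(spec, noise, variance=0.5, quantile=1e-12)
        valid = ~np.isnan(sig.observed_power)
        assert sig.significant[valid].all()

    def test_mismatched_lengths_rejected(self, cosine_series):
        spec = cwt(cosine_series)
        noise = RedNoiseModel.from_alpha(0.3, cosine_series.n + 1)
        with pytest.raises(ValidationError):
            significance_curve(spec, noise, variance=1.0)

    def test_significant_iff_observed_exceeds_threshold(self, wt_series):
        det = preprocess(wt_series)
        spec = cwt(det.smoothed)
        noise = RedNoiseModel.from_alpha(0.5, det.smoothed.n)
        sig = significance_curve(spec, noise, float(np.var(det.smoothed.values, ddof=1)))
        valid = ~np.isnan(sig.observed_power)
        np.testing.assert_array_equal(
            sig.significant[valid], sig.observed_power[valid] > sig.threshold[valid]
        )
        assert np.all(sig.threshold > 0)


class TestRhythmTest:
    @staticmethod
    def run_on_raw(series, window=100, **kwargs):
        det = preprocess(series, window=window)
        return rhythm_test(
            det.smoothed, background_series=det.relative,
            smoothing_window=window, **kwargs,
        )

    def test_wt_like_series_detected_near_24h(self, wt_series):
        result = self.run_on_raw(wt_series)
        assert result.is_rhythmic
        step = 2**0.125
        assert 24 / step**2 <= result.best_period_h <= 24 * step**2

    def test_null_series_mostly_not_significant(self):
        cfg = SyntheticConfig(seed=101)
        hits = 0
        for s in generate_null_series(5, cfg):
            hits += self.run_on_raw(s).is_rhythmic
        assert hits <= 1

    def test_out_of_band_oscillation_is_not_circadian(self):
        cfg = SyntheticConfig(
            duration_h=120, trend_coeffs=(0.0,), osc_period_h=6.0,
            osc_amplitude=3.0, noise_alpha=0.3, noise_sigma=0.1, seed=4,
        )
        result = self.run_on_raw(generate_series(cfg))
        assert not result.is_rhythmic

    def test_observed_in_band_power_monotone_in_amplitude(self):
        powers = []
        for amp in (0.5, 1.0, 2.0, 4.0):
            cfg = SyntheticConfig(seed=55, osc_amplitude=amp)
            det = preprocess(generate_series(cfg))
            spec = cwt(det.smoothed)
            band = (spec.periods >= 18) & (spec.periods <= 32)
            mask = spec.coi_mask()
            obs = np.nanmean(np.where(mask, spec.power, np.nan), axis=1)
            powers.append(np.nanmax(obs[band]))
        assert np.all(np.diff(powers) > 0)


def test_pointwise_null_coverage_small_scale():
    """~95% of AR(1) power values fall below the 95% level (known alpha)."""
    from circascan import ar1_calibration_config, null_coverage_percent

    cfg = ar1_calibration_config(n_samples=1024, seed=6)
    coverage = null_coverage_percent(30, cfg)
    assert coverage == pytest.approx(95.0, abs=1.5)


def test_default_scale_grid_spans_circadian_band():
    scales = default_scales(dt_h=1 / 30)
    periods = scales * morlet_fourier_factor()
    assert periods[0] <= 2.0 and periods[-1] >= 32.0
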