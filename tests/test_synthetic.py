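"""Generator contracts: deterministic components, AR(1) statistics, seeding."""

import dataclasses

import numpy as np
import pytest

from circascan import (
    ConfigurationError,
    SyntheticConfig,
    generate_entrainment_pair,
    generate_null_series,
    generate_series,
)
from circascan.synthetic import deterministic_components


def test_constant_config_gives_constant_series():
    cfg = SyntheticConfig(
        duration_h=10, dt_h=0.5, trend_coeffs=(5.0,), osc_amplitude=0.0,
        noise_sigma=0.0, seed=0,
    )
    s = generate_series(cfg)
    assert s.n == int(np.floor(10 / 0.5)) + 1
    np.testing.assert_allclose(s.values, 5.0)


def test_cosine_extrema_at_period_multiples():
    cfg = SyntheticConfig(
        duration_h=48, dt_h=1.0, trend_coeffs=(0.0,), osc_amplitude=1.0,
        osc_period_h=24.0, osc_phase_h=0.0, noise_sigma=0.0, seed=0,
    )
    s = generate_series(cfg)
    at = {t: s.values[np.argmin(np.abs(s.times - t))] for t in (0, 12, 24, 36, 48)}
    np.testing.assert_allclose([at[0], at[24], at[48]], 1.0, atol=1e-12)
    np.testing.assert_allclose([at[12], at[36]], -1.0, atol=1e-12)


def test_noise_residual_mean_within_standard_error():
    """(series - trend - oscillation) is stationary AR(1): mean ~ 0."""
    cfg = SyntheticConfig(
        duration_h=200, dt_h=1 / 30, trend_coeffs=(1.0, 0.5, -0.01, 1e-4, -1e-7),
        osc_amplitude=3.0, osc_period_h=24.0, noise_alpha=0.7, noise_sigma=0.2,
        seed=1,
    )
    s = generate_series(cfg)
    _, trend, osc = deterministic_components(cfg)
    resid = s.values - trend - osc
    n = resid.size
    assert n >= 5000
    sd_stat = cfg.noise_sigma / np.sqrt(1 - cfg.noise_alpha**2)
    # variance of the mean of AR(1): (sd^2/n) (1+alpha)/(1-alpha)
    se = sd_stat * np.sqrt((1 + cfg.noise_alpha) / (1 - cfg.noise_alpha) / n)
    assert abs(resid.mean()) < 3 * se


@pytest.mark.parametrize("alpha", [0.0, 0.7])
def test_null_series_lag1_autocorrelation(alpha):
    cfg = SyntheticConfig(
        duration_h=(10_000 - 1) / 30, dt_h=1 / 30, trend_coeffs=(2.0, 0.1),
        noise_alpha=alpha, noise_sigma=1.0, seed=7,
    )
    (s,) = generate_null_series(1, cfg)
    _, trend, _ = deterministic_components(dataclasses.replace(cfg, osc_amplitude=0.0))
    x = s.values - trend
    x = x - x.mean()
    r1 = np.dot(x[:-1], x[1:]) / np.dot(x, x)
    se = np.sqrt((1 - alpha**2) / x.size) if alpha > 0 else 1 / np.sqrt(x.size)
    assert abs(r1 - alpha) < 3 * se


def test_stationary_variance_matches_ar1_formula():
    cfg = SyntheticConfig(
        duration_h=(50_000 - 1) / 30, dt_h=1 / 30, trend_coeffs=(0.0,),
        osc_amplitude=0.0, noise_alpha=0.6, noise_sigma=0.5, seed=3,
    )
    s = generate_series(cfg)
    expected = cfg.noise_sigma**2 / (1 - cfg.noise_alpha**2)
    assert np.var(s.values) == pytest.approx(expected, rel=0.10)


def test_periodogram_peak_at_configured_frequency(cosine_series):
    mag = np.abs(np.fft.rfft(cosine_series.values))
    freqs = np.fft.rfftfreq(cosine_series.n, cosine_series.dt_h)
    assert freqs[np.argmax(mag)] == pytest.approx(1 / 24.0, abs=freqs[1] / 2)


def test_trend_only_output_equals_polynomial_exactly():
    coeffs = (2.0, -0.3, 0.004)
    cfg = SyntheticConfig(
        duration_h=100, dt_h=0.25, trend_coeffs=coeffs, osc_amplitude=0.0,
        noise_sigma=0.0, seed=0,
    )
    s = generate_series(cfg)
    expected = np.polynomial.polynomial.polyval(s.times, np.asarray(coeffs))
    np.testing.assert_array_equal(s.values, expected)


def test_determinism_bit_identical():
    cfg = SyntheticConfig(seed=42, duration_h=48)
    a, b = generate_series(cfg), generate_series(cfg)
    np.testing.assert_array_equal(a.values, b.values)
    c = generate_series(dataclasses.replace(cfg, seed=43))
    assert not np.array_equal(a.values, c.values)


def test_lowdensity_noise_only_below_cutoff():
    base = SyntheticConfig(
        duration_h=100, dt_h=0.1, trend_coeffs=(0.0, 1.0), osc_amplitude=0.0,
        noise_sigma=0.0, seed=5,
    )
    noisy = dataclasses.replace(base, lowdensity_noise_sigma=2.0, lowdensity_cutoff=50.0)
    clean = generate_series(base)
    s = generate_series(noisy)
    cut = s.times < 50.0 / 1.0  # trend = t here
    assert np.any(s.values[cut] != clean.values[cut])
    np.testing.assert_array_equal(s.values[~cut], clean.values[~cut])


class TestEntrainmentPair:
    def test_noiseless_peaks_offset_by_shift(self):
        cfg = SyntheticConfig(
            duration_h=96, dt_h=1 / 30, trend_coeffs=(0.0,), osc_amplitude=1.0,
            noise_sigma=0.0, seed=0,
        )
        a, b = generate_entrainment_pair(cfg, 12.0)
        ta = a.times[np.argmax(a.values[: 24 * 30])]
        tb = b.times[np.argmax(b.values[: 36 * 30])]
        assert (tb - ta) % 24 == pytest.approx(12.0, abs=a.dt_h)

    def test_zero_shift_identical_deterministic_components(self):
        cfg = SyntheticConfig(
            duration_h=72, trend_coeffs=(1.0, 0.2), osc_amplitude=2.0,
            noise_sigma=0.0, seed=9,
        )
        a, b = generate_entrainment_pair(cfg, 0.0)
        np.testing.assert_allclose(a.values, b.values, atol=1e-12)

    def test_full_period_shift_is_zero_mod_period(self):
        cfg = SyntheticConfig(
            duration_h=72, trend_coeffs=(0.0,), osc_amplitude=1.0,
            noise_sigma=0.0, seed=0,
        )
        a, b = generate_entrainment_pair(cfg, 24.0)
        np.testing.assert_allclose(a.values, b.values, atol=1e-9)

    def test_negative_shift_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_entrainment_pair(SyntheticConfig(), -1.0)


class TestNullSeries:
    def test_amplitude_forced_to_zero_and_reproducible(self):
        cfg = SyntheticConfig(duration_h=48, osc_amplitude=5.0, seed=2)
        first = generate_null_series(5, cfg)
        again = generate_null_series(5, cfg)
        assert len(first) == 5
        for s, t in zip(first, again):
            np.testing.assert_array_equal(s.values, t.values)
        values = [tuple(s.values[:10]) for s in first]
        assert len(set(values)) == 5  # distinct noise streams

    def test_n_series_validation(self):
        with pytest.raises(ConfigurationError):
            generate_null_series(0, SyntheticConfig())


@pytest.mark.parametrize(
    "kwargs",
    [
        {"dt_h": 0.0},
        {"duration_h": -1.0},
        {"noise_alpha": 1.0},
        {"noise_alpha": -0.1},
        {"osc_amplitude": -1.0},
        {"osc_period_h": 0.0},
    ],
)
def test_invalid_configs_rejected(kwargs):
    with pytest.raises(ConfigurationError):
        SyntheticConfig(**kwargs)


def test_config_ini_round_trip(tmp_path):
    cfg = SyntheticConfig(duration_h=120, osc_period_h=None, seed=17,
                          trend_coeffs=(1.0, 2.0, 3.0))
    path = tmp_path / "cfg.ini"
    cfg.to_file(path)
    assert SyntheticConfig.from_file(path) == cfg
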