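"""Synthetic backscatter generator.

Online backscatter traces of growing cyanobacterial batch cultures show a
multi-day growth trend with a superimposed ~24 h oscillation and serially
correlated sensor noise; young, optically thin cultures are additionally
noisier because surface reflections contribute more to the signal. This
module generates series with exactly that structure so every analysis stage
can be exercised and calibrated without instrument data:

    value(t) = trend(t) + A exp(-d t) cos(2 pi (t - phi) / P) + AR(1) noise
               (+ extra white noise while the trend is below a density cutoff)

The AR(1) noise x_n = alpha x_{n-1} + z_n (z_n Gaussian) is the same
red-noise process used as the null background in the wavelet significance
test, so null series drawn here are exactly the calibration target of that
test. The AR(1) state is initialized from its stationary distribution
(variance sigma^2 / (1 - alpha^2)): generated noise is stationary from the
first sample and calibration statistics need no burn-in.

All randomness flows from ``SyntheticConfig.seed``; identical configs give
bit-identical series.
"""

from __future__ import annotations

import configparser
import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

from .errors import ConfigurationError
from .series import UniformSeries

#: 2-minute sampling expressed in hours
DT_2MIN_H = 1.0 / 30.0


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic backscatter model.

    Defaults describe a wild-type-like culture followed for 10 days at
    2-minute sampling: a gently accelerating growth trend rising ~3 a.u./h,
    a sustained 24 h oscillation of 3 a.u. amplitude, and red noise with
    lag-1 autocorrelation 0.7 and innovation s.d. 0.2 a.u. (stationary
    s.d. ~0.28 a.u., clearly visible but far below the oscillation).

    Attributes
    ----------
    duration_h : float
        Total duration in hours (> 0). The series has
        ``floor(duration_h / dt_h) + 1`` samples starting at t = 0.
    dt_h : float
        Sampling step in hours; default 1/30 h (2 min).
    trend_coeffs : tuple of float
        Polynomial growth-trend coefficients, a.u. per hour^j, ascending
        (``trend(t) = sum_j c_j t**j`` with t in hours).
    osc_period_h : float or None
        Oscillation period in hours; ``None`` disables the oscillation.
    osc_amplitude : float
        Oscillation amplitude in a.u. (>= 0).
    osc_phase_h : float
        Time of the (undamped) oscillation peak, hours after t = 0.
    damping_rate : float
        Exponential amplitude decay per hour (>= 0, default 0: sustained).
    noise_alpha : float
        Lag-1 autocorrelation of the AR(1) noise, in [0, 1).
    noise_sigma : float
        Innovation standard deviation of the AR(1) noise, a.u. (>= 0).
    lowdensity_noise_sigma : float
        S.d. of extra white noise added while the *trend* is below
        ``lowdensity_cutoff`` (surface reflections in thin cultures). Gated
        on the deterministic trend, not the noisy value, for reproducibility.
    lowdensity_cutoff : float
        Trend level (a.u.) below which the extra noise applies.
    seed : int
        Seed for all random draws.
    """

    duration_h: float = 240.0
    dt_h: float = DT_2MIN_H
    trend_coeffs: tuple = (20.0, 2.98, 0.005, 0.0, 0.0)
    osc_period_h: float | None = 24.0
    osc_amplitude: float = 3.0
    osc_phase_h: float = 0.0
    damping_rate: float = 0.0
    noise_alpha: float = 0.7
    noise_sigma: float = 0.2
    lowdensity_noise_sigma: float = 0.0
    lowdensity_cutoff: float = 0.0
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "trend_coeffs", tuple(float(c) for c in self.trend_coeffs))
        self.validate()

    def validate(self) -> None:
        if not self.duration_h > 0:
            raise ConfigurationError(f"duration_h must be > 0, got {self.duration_h}")
        if not self.dt_h > 0:
            raise ConfigurationError(f"dt_h must be > 0, got {self.dt_h}")
        if self.osc_period_h is not None and not self.osc_period_h > 0:
            raise ConfigurationError(f"osc_period_h must be > 0 or None, got {self.osc_period_h}")
        if self.osc_amplitude < 0:
            raise ConfigurationError(f"osc_amplitude must be >= 0, got {self.osc_amplitude}")
        if not 0.0 <= self.noise_alpha < 1.0:
            raise ConfigurationError(f"noise_alpha must be in [0, 1), got {self.noise_alpha}")
        if self.noise_sigma < 0:
            raise ConfigurationError(f"noise_sigma must be >= 0, got {self.noise_sigma}")
        if self.damping_rate < 0:
            raise ConfigurationError(f"damping_rate must be >= 0, got {self.damping_rate}")
        if self.lowdensity_noise_sigma < 0:
            raise ConfigurationError("lowdensity_noise_sigma must be >= 0")

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["trend_coeffs"] = list(self.trend_coeffs)
        return d

    def to_file(self, path) -> None:
        """Write as a flat INI file (section ``[synthetic]``)."""
        cp = configparser.ConfigParser()
        cp["synthetic"] = {
            k: (",".join(repr(c) for c in v) if k == "trend_coeffs" else repr(v))
            for k, v in self.to_dict().items()
        }
        with open(path, "w") as fh:
            cp.write(fh)

    @classmethod
    def from_file(cls, path) -> "SyntheticConfig":
        cp = configparser.ConfigParser()
        read = cp.read(path)
        if not read or "synthetic" not in cp:
            raise ConfigurationError(f"no [synthetic] section in {path}")
        raw = dict(cp["synthetic"])
        kwargs: dict = {}
        for f in dataclasses.fields(cls):
            if f.name not in raw:
                continue
            text = raw[f.name]
            if f.name == "trend_coeffs":
                kwargs[f.name] = tuple(float(c) for c in text.split(","))
            elif f.name == "seed":
                kwargs[f.name] = int(text)
            elif f.name == "osc_period_h":
                kwargs[f.name] = None if text == "None" else float(text)
            else:
                kwargs[f.name] = float(text)
        return cls(**kwargs)

    # -- convenience factories ----------------------------------------

    @classmethod
    def wt_like(cls, seed: int = 0, **overrides) -> "SyntheticConfig":
        """Wild-type-like defaults (sustained 24 h oscillation on a growth trend)."""
        return cls(seed=seed, **overrides)

    @classmethod
    def null_like(cls, seed: int = 0, **overrides) -> "SyntheticConfig":
        """Arrhythmic mutant-like series: trend + red noise, no oscillation."""
        overrides.setdefault("osc_amplitude", 0.0)
        return cls(seed=seed, **overrides)


def _time_grid(config: SyntheticConfig) -> np.ndarray:
    n = int(np.floor(config.duration_h / config.dt_h)) + 1
    return np.arange(n) * config.dt_h


def deterministic_components(config: SyntheticConfig):
    """Return (times, trend, oscillation) without any noise."""
    t = _time_grid(config)
    trend = np.polynomial.polynomial.polyval(t, np.asarray(config.trend_coeffs))
    if config.osc_period_h is not None and config.osc_amplitude > 0:
        osc = (
            config.osc_amplitude
            * np.exp(-config.damping_rate * t)
            * np.cos(2.0 * np.pi * (t - config.osc_phase_h) / config.osc_period_h)
        )
    else:
        osc = np.zeros_like(t)
    return t, trend, osc


def _ar1_noise(rng: np.random.Generator, n: int, alpha: float, sigma: float) -> np.ndarray:
    if sigma == 0.0:
        return np.zeros(n)
    sd_stat = sigma / np.sqrt(1.0 - alpha * alpha)
    x0 = rng.normal(0.0, sd_stat)
    z = rng.normal(0.0, sigma, n - 1)
    if alpha == 0.0:
        return np.concatenate(([x0], z))
    # x_n = alpha x_{n-1} + z_n as an IIR filter seeded with the stationary x0
    rest, _ = lfilter([1.0], [1.0, -alpha], z, zi=np.array([alpha * x0]))
    return np.concatenate(([x0], rest))


def generate_series(config: SyntheticConfig, label: str | None = None) -> UniformSeries:
    """Generate one synthetic backscatter series.

    The output is trend + (damped) cosine + stationary AR(1) noise, plus
    optional extra white noise on the low-density (early-growth) samples.
    """
    config.validate()
    t, trend, osc = deterministic_components(config)
    rng = np.random.default_rng(config.seed)
    noise = _ar1_noise(rng, t.size, config.noise_alpha, config.noise_sigma)
    values = trend + osc + noise
    if config.lowdensity_noise_sigma > 0:
        extra = rng.normal(0.0, config.lowdensity_noise_sigma, t.size)
        values = values + np.where(trend < config.lowdensity_cutoff, extra, 0.0)
    if label is None:
        label = f"synthetic(seed={config.seed})"
    return UniformSeries(times=t, values=values, dt_h=config.dt_h, label=label)


def _child_seeds(seed: int, n: int) -> list[int]:
    state = np.random.SeedSequence(int(seed)).generate_state(n, np.uint32)
    return [int(s) for s in state]


def generate_entrainment_pair(
    config: SyntheticConfig, shift_h: float
) -> tuple[UniformSeries, UniformSeries]:
    """Two cultures identical except for an oscillation phase shift.

    Emulates the dilution / light-dark entrainment experiments in which a
    second culture is synchronized `shift_h` hours later: same trend,
    amplitude, period and noise statistics, independent noise streams, and
    noiseless peak times offset by ``shift_h`` modulo the period.
    """
    if shift_h < 0:
        raise ConfigurationError(f"shift_h must be >= 0, got {shift_h}")
    seed_a, seed_b = _child_seeds(config.seed, 2)
    a = generate_series(
        dataclasses.replace(config, seed=seed_a), label=f"{config.seed}/reference"
    )
    b = generate_series(
        dataclasses.replace(
            config, seed=seed_b, osc_phase_h=config.osc_phase_h + shift_h
        ),
        label=f"{config.seed}/shifted+{shift_h}h",
    )
    return a, b


def generate_null_series(n_series: int, config: SyntheticConfig) -> list[UniformSeries]:
    """Arrhythmic (oscillation-free) series for significance calibration.

    The oscillation amplitude is forced to zero regardless of `config`;
    per-series seeds are derived deterministically from ``config.seed``.
    """
    if n_series < 1:
        raise ConfigurationError(f"n_series must be >= 1, got {n_series}")
    seeds = _child_seeds(config.seed, n_series)
    out = []
    for i, s in enumerate(seeds):
        c = dataclasses.replace(config, osc_amplitude=0.0, seed=s)
        out.append(generate_series(c, label=f"null[{i}](seed={s})"))
    return out
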