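"""Raw-signal conditioning: detrend, normalize, smooth, find peaks.

A raw backscatter trace is dominated by the multi-day growth of the culture;
the circadian component rides on top of it. The standard conditioning chain
is (1) subtract a least-squares polynomial growth trend (degree 4 by
default), (2) subtract the arithmetic mean of the residual, (3) apply a
centered moving average (window 100 samples by default, ~3.3 h at 2-min
sampling) and drop the half-window of edge-contaminated samples on each side
(50 samples, ~1.7 h).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.signal

from .errors import InsufficientDataError, ValidationError
from .series import UniformSeries

DEFAULT_DETREND_DEGREE = 4
DEFAULT_SMOOTH_WINDOW = 100
DEFAULT_MIN_PEAK_SEPARATION_H = 12.0


@dataclass(frozen=True)
class DetrendResult:
    """Outcome of the detrend (and optionally smooth) stage.

    `relative` is the mean-subtracted residual around the polynomial trend;
    `smoothed` (if present) is its moving average with ``trimmed_per_side``
    samples removed at each end.
    """

    degree: int
    trend_coeffs: np.ndarray  # ascending powers of time in hours (a.u. / h^j)
    raw: UniformSeries
    relative: UniformSeries
    smoothed: UniformSeries | None = None
    window: int | None = None
    trimmed_per_side: int = 0

    @property
    def trend_values(self) -> np.ndarray:
        return np.polynomial.polynomial.polyval(self.raw.times, self.trend_coeffs)


def detrend(series: UniformSeries, degree: int = DEFAULT_DETREND_DEGREE) -> DetrendResult:
    """Remove a least-squares polynomial trend and center the residual.

    The polynomial is fitted on time rescaled to [-1, 1] for conditioning
    (a degree-4 fit over hundreds of hours is ill-conditioned in the raw
    hour basis) and the coefficients are converted back to the hour basis.
    The returned relative signal has exactly zero arithmetic mean to
    numerical tolerance.
    """
    if degree < 0:
        raise ValidationError(f"degree must be >= 0, got {degree}")
    if series.n <= degree + 1:
        raise InsufficientDataError(
            f"need more than degree+1={degree + 1} samples, got {series.n}"
        )
    fit = np.polynomial.Polynomial.fit(series.times, series.values, degree)
    trend = fit(series.times)
    resid = series.values - trend
    relative = resid - resid.mean()
    coeffs = fit.convert().coef
    # pad so coeffs always has degree+1 entries
    if coeffs.size < degree + 1:
        coeffs = np.pad(coeffs, (0, degree + 1 - coeffs.size))
    return DetrendResult(
        degree=degree,
        trend_coeffs=coeffs,
        raw=series,
        relative=series.with_values(relative, label=f"{series.label}/relative"),
    )


def _smoothing_kernel(window: int) -> np.ndarray:
    """Centered moving-average kernel of total weight 1.

    Odd windows use the plain ``window``-point boxcar. Even windows use the
    classic centered even-order moving average: ``window + 1`` taps with the
    two end taps at half weight, which keeps the filter symmetric (zero
    phase) and exact on affine signals while trimming ``window/2`` samples
    per side.
    """
    if window % 2 == 1:
        return np.full(window, 1.0 / window)
    k = np.full(window + 1, 1.0 / window)
    k[0] *= 0.5
    k[-1] *= 0.5
    return k


def smooth(series: UniformSeries, window: int = DEFAULT_SMOOTH_WINDOW) -> UniformSeries:
    """Centered moving average; trims floor(window/2) samples per side.

    Output times are the retained original times. ``window=1`` is the
    identity.
    """
    if window < 1:
        raise ValidationError(f"window must be >= 1, got {window}")
    if series.n <= window:
        raise InsufficientDataError(
            f"series of {series.n} samples too short for window {window}"
        )
    if window == 1:
        return series.with_values(series.values, label=f"{series.label}/smoothed")
    half = window // 2
    kernel = _smoothing_kernel(window)
    smoothed = np.convolve(series.values, kernel, mode="valid")
    return UniformSeries(
        times=series.times[half: series.n - half],
        values=smoothed,
        dt_h=series.dt_h,
        label=f"{series.label}/smoothed",
    )


def preprocess(
    series: UniformSeries,
    degree: int = DEFAULT_DETREND_DEGREE,
    window: int = DEFAULT_SMOOTH_WINDOW,
) -> DetrendResult:
    """Full conditioning chain: detrend -> mean-subtract -> smooth -> trim."""
    result = detrend(series, degree)
    smoothed = smooth(result.relative, window)
    return DetrendResult(
        degree=result.degree,
        trend_coeffs=result.trend_coeffs,
        raw=result.raw,
        relative=result.relative,
        smoothed=smoothed,
        window=window,
        trimmed_per_side=window // 2,
    )


def smoothing_gain(window: int, dt_h: float):
    """Squared frequency response |H(f)|^2 of the smoothing filter.

    Returns a vectorized callable of frequency (1/hours). Used to shape the
    red-noise background spectrum when significance is assessed on the
    *smoothed* signal: the moving average suppresses high-frequency noise,
    so the null spectrum of the smoothed series is the AR(1) spectrum times
    this gain.
    """
    kernel = _smoothing_kernel(window)
    half = (kernel.size - 1) // 2
    lags = np.arange(-half, half + 1) * dt_h

    def gain(freq):
        freq = np.atleast_1d(np.asarray(freq, dtype=float))
        # kernel is symmetric, so H is real
        h = np.cos(2.0 * np.pi * freq[:, None] * lags[None, :]) @ kernel
        return h * h

    return gain


def find_peaks(
    series: UniformSeries,
    min_separation_h: float = DEFAULT_MIN_PEAK_SEPARATION_H,
    prominence: float | None = None,
) -> list[float]:
    """Times (hours) of local maxima at least ``min_separation_h`` apart.

    Conflicting peaks are resolved greedily in favor of the higher one.
    On a flat plateau the leftmost sample is reported. Boundary samples are
    never peaks; an empty list is a valid result (e.g. monotone input).
    ``prominence`` (a.u.), when given, additionally discards shallow bumps —
    useful to reject noise-induced maxima in trough regions, which a pure
    separation rule cannot.
    """
    if series.n < 3:
        raise InsufficientDataError("need at least 3 samples to find peaks")
    if min_separation_h < 0:
        raise ValidationError("min_separation_h must be >= 0")
    distance = min_separation_h / series.dt_h
    kwargs = {"plateau_size": (1, None)}
    if prominence is not None:
        kwargs["prominence"] = prominence
    if distance >= 1:
        kwargs["distance"] = distance
    idx, props = scipy.signal.find_peaks(series.values, **kwargs)
    left = props.get("left_edges", idx)
    return [float(series.times[i]) for i in left]
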