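"""Peak-based phase comparison and growth-rate estimation.

Entrainment experiments (staggered dilution, shifted light-dark cycles) and
the comparison between backscatter and KaiC3 phosphorylation rhythms are
both read out as the time offset between oscillation peaks. Offsets are
circular quantities: a shift is reported wrapped into (-period/2, period/2],
with the boundary case (e.g. a 12 h shift of a 24 h rhythm) mapping to
+period/2 by convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .errors import InsufficientDataError, NoPhaseError, ValidationError
from .preprocessing import find_peaks
from .series import UniformSeries

PHOSPHO_FIT_DEGREE = 5
_PEAK_GRID_STEP_H = 0.01


@dataclass(frozen=True)
class PhaseComparison:
    peaks_a: list[float]
    peaks_b: list[float]
    offset_h: float            # circular mean of peak-to-peak shifts, in (-P/2, P/2]
    period_h: float


@dataclass(frozen=True)
class PhosphoSeries:
    """Phosphorylation-ratio time course with its polynomial summary fit.

    ``replicate_ratios`` holds the per-replicate P-KaiC3 / total-KaiC3
    ratios (one column per replicate); the degree-5 polynomial is fitted to
    the per-time replicate means and its maximum inside the sampled window
    is the fitted peak time.
    """

    times: np.ndarray
    replicate_ratios: np.ndarray      # (n_times, n_replicates), in [0, 1]
    mean_ratio: np.ndarray
    fit_degree: int
    fit_coeffs: np.ndarray            # highest power first (polyfit order)
    fitted_peak_time_h: float

    def fitted(self, t) -> np.ndarray:
        return np.polyval(self.fit_coeffs, np.asarray(t, dtype=float))


def _wrap(delta: float, period: float) -> float:
    """Wrap into (-period/2, period/2]; the boundary maps to +period/2."""
    r = (delta + 0.5 * period) % period - 0.5 * period
    if r <= -0.5 * period + 1e-12 * period:
        r += period
    return r


def phase_offset(
    series_a: UniformSeries,
    series_b: UniformSeries,
    period_h: float = 24.0,
    min_separation_h: float | None = None,
) -> PhaseComparison:
    """Circular phase offset (b relative to a) from matched oscillation peaks.

    Peaks are detected in both smoothed relative signals; each peak of `a`
    is matched to the nearest peak of `b` in wrapped time, and the offset is
    the circular mean of the wrapped differences. A positive offset means
    `b` peaks later than `a` (so `b` lags, equivalently `a` phase-advances
    `b`).
    """
    if period_h <= 0:
        raise ValidationError("period_h must be > 0")
    if min_separation_h is None:
        min_separation_h = 0.5 * period_h
    peaks_a = find_peaks(series_a, min_separation_h)
    peaks_b = find_peaks(series_b, min_separation_h)
    if not peaks_a or not peaks_b:
        raise NoPhaseError(
            f"no peaks detected ({len(peaks_a)} in a, {len(peaks_b)} in b)"
        )
    pb = np.asarray(peaks_b)
    diffs = []
    for pa in peaks_a:
        wrapped = np.array([_wrap(b - pa, period_h) for b in pb])
        diffs.append(wrapped[np.argmin(np.abs(wrapped))])
    theta = 2.0 * np.pi * np.asarray(diffs) / period_h
    c, s = float(np.mean(np.cos(theta))), float(np.mean(np.sin(theta)))
    if np.hypot(c, s) < 1e-12:
        raise NoPhaseError("peak offsets cancel; phase undefined")
    offset = np.arctan2(s, c) * period_h / (2.0 * np.pi)
    if offset <= -0.5 * period_h:
        offset += period_h
    return PhaseComparison(
        peaks_a=peaks_a, peaks_b=peaks_b, offset_h=float(offset), period_h=float(period_h)
    )


def fit_phospho(times, replicate_ratios) -> PhosphoSeries:
    """Degree-5 polynomial summary of replicate phosphorylation ratios.

    ``replicate_ratios`` is an (n_times, n_replicates) table (or DataFrame)
    of ratios in [0, 1]. The polynomial is fitted to the per-time arithmetic
    means — a smooth, outlier-insensitive summary of the cycle — and the
    fitted peak is located on a 0.01 h grid restricted to the sampled
    interval (a degree-5 polynomial diverges outside it).
    """
    times = np.asarray(times, dtype=float)
    ratios = np.asarray(
        replicate_ratios.values if isinstance(replicate_ratios, pd.DataFrame) else replicate_ratios,
        dtype=float,
    )
    if ratios.ndim == 1:
        ratios = ratios[:, None]
    if ratios.shape[0] != times.size:
        raise ValidationError(
            f"{times.size} time points but {ratios.shape[0]} ratio rows"
        )
    if np.unique(times).size < PHOSPHO_FIT_DEGREE + 2:
        raise InsufficientDataError(
            f"need at least {PHOSPHO_FIT_DEGREE + 2} distinct time points"
        )
    if np.any(~np.isfinite(ratios)) or ratios.min() < 0 or ratios.max() > 1:
        raise ValidationError("ratios must be finite and within [0, 1]")
    mean = ratios.mean(axis=1)
    coeffs = np.polyfit(times, mean, PHOSPHO_FIT_DEGREE)
    grid = np.arange(times.min(), times.max() + _PEAK_GRID_STEP_H / 2, _PEAK_GRID_STEP_H)
    fitted = np.polyval(coeffs, grid)
    peak_time = float(grid[np.argmax(fitted)])
    return PhosphoSeries(
        times=times,
        replicate_ratios=ratios,
        mean_ratio=mean,
        fit_degree=PHOSPHO_FIT_DEGREE,
        fit_coeffs=coeffs,
        fitted_peak_time_h=peak_time,
    )


def growth_rate(series: UniformSeries, start_h: float) -> float:
    """OLS slope (a.u. per hour) of the raw backscatter from ``start_h`` on.

    Estimates the linear growth rate of the culture once it has left the
    lag phase; the ~24 h oscillation averages out over whole cycles.
    """
    if not series.times[0] <= start_h <= series.times[-1]:
        raise ValidationError(
            f"start_h={start_h} outside series range "
            f"[{series.times[0]}, {series.times[-1]}]"
        )
    mask = series.times >= start_h
    if mask.sum() < 10:
        raise InsufficientDataError(
            f"only {int(mask.sum())} samples after start_h={start_h}; need >= 10"
        )
    fit = scipy.stats.linregress(series.times[mask], series.values[mask])
    return float(fit.slope)
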