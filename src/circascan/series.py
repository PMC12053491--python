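"""Uniformly sampled time series container.

Everything downstream (detrending, wavelet and Fourier analysis, phase
comparison) assumes a strictly uniform time grid in hours; this module
provides the validated container those stages share.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ValidationError

#: relative tolerance on the uniformity of the sampling grid
_GRID_RTOL = 1e-6


@dataclass(frozen=True)
class UniformSeries:
    """A uniformly sampled scalar time series.

    Parameters
    ----------
    times
        Sample times in hours, strictly increasing with uniform step.
    values
        Measured values in arbitrary units (a.u.).
    dt_h
        Sampling interval in hours. If omitted it is inferred from `times`.
    label
        Free-text label carried through the pipeline (e.g. "WT 30C").
    """

    times: np.ndarray
    values: np.ndarray
    dt_h: float = 0.0
    label: str = ""

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if times.ndim != 1 or values.ndim != 1:
            raise ValidationError("times and values must be one-dimensional")
        if times.size != values.size:
            raise ValidationError(
                f"times (n={times.size}) and values (n={values.size}) differ in length"
            )
        if times.size < 2:
            raise ValidationError("a uniform series needs at least 2 samples")
        if not np.all(np.isfinite(values)):
            bad = int(np.flatnonzero(~np.isfinite(values))[0])
            raise ValidationError(f"non-finite value at sample {bad}")
        if not np.all(np.isfinite(times)):
            raise ValidationError("non-finite time stamp")
        diffs = np.diff(times)
        dt = float(self.dt_h) if self.dt_h else float(np.median(diffs))
        if dt <= 0:
            raise ValidationError("sampling step must be positive")
        dev = np.abs(diffs - dt)
        if np.any(diffs <= 0):
            bad = int(np.flatnonzero(diffs <= 0)[0]) + 1
            raise ValidationError(f"non-increasing time at sample {bad}")
        if dev.max() > _GRID_RTOL * dt:
            bad = int(np.argmax(dev)) + 1
            raise ValidationError(
                f"non-uniform sampling step at sample {bad}: "
                f"step {diffs[bad - 1]:.6g} h vs expected {dt:.6g} h"
            )
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "dt_h", dt)

    @classmethod
    def from_values(cls, values, dt_h: float, t0: float = 0.0, label: str = "") -> "UniformSeries":
        """Build a series from values and a sampling step, times starting at `t0`."""
        values = np.asarray(values, dtype=float)
        times = t0 + np.arange(values.size) * float(dt_h)
        return cls(times=times, values=values, dt_h=float(dt_h), label=label)

    @property
    def n(self) -> int:
        return int(self.times.size)

    @property
    def duration_h(self) -> float:
        return float(self.times[-1] - self.times[0])

    def with_values(self, values, label: str | None = None) -> "UniformSeries":
        """Same time grid, new values."""
        return UniformSeries(
            times=self.times,
            values=np.asarray(values, dtype=float),
            dt_h=self.dt_h,
            label=self.label if label is None else label,
        )

    def slice_time(self, start_h: float | None = None, stop_h: float | None = None) -> "UniformSeries":
        """Sub-series with start_h <= t <= stop_h."""
        mask = np.ones(self.n, dtype=bool)
        if start_h is not None:
            mask &= self.times >= start_h
        if stop_h is not None:
            mask &= self.times <= stop_h
        if mask.sum() < 2:
            raise ValidationError("time slice leaves fewer than 2 samples")
        return UniformSeries(self.times[mask], self.values[mask], self.dt_h, self.label)
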