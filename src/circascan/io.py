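"""Reading and writing the package's delimited-text formats.

Series files are two-column delimited text with a header
(``time_h,backscatter_au``); phosphorylation tables are
``time_h,rep1,rep2,...``. Validation errors name the first offending row
(1-based, counting the header as row 1).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .series import UniformSeries

_SEPARATORS = {"csv": ",", "tsv": "\t"}


def _read_table(path, dialect: str | None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    if dialect is None:
        dialect = "tsv" if path.suffix.lower() in {".tsv", ".tab"} else "csv"
    if dialect not in _SEPARATORS:
        raise ValidationError(f"unknown dialect {dialect!r}; use 'csv' or 'tsv'")
    try:
        frame = pd.read_csv(path, sep=_SEPARATORS[dialect])
    except pd.errors.EmptyDataError:
        raise ValidationError(f"empty file: {path}") from None
    if frame.shape[0] == 0:
        raise ValidationError(f"no data rows in {path}")
    return frame


def read_series(path, dialect: str | None = None, label: str | None = None) -> UniformSeries:
    """Read a two-column time/value file into a validated uniform series.

    The dialect (comma vs tab) is inferred from the extension unless given.
    Non-numeric cells, missing values, non-monotone or non-uniform time
    steps raise :class:`ValidationError` naming the first offending row.
    """
    frame = _read_table(path, dialect)
    if frame.shape[1] < 2:
        raise ValidationError(
            f"{path}: need two columns (time, value), found {frame.shape[1]}"
        )
    times = pd.to_numeric(frame.iloc[:, 0], errors="coerce").to_numpy(dtype=float)
    values = pd.to_numeric(frame.iloc[:, 1], errors="coerce").to_numpy(dtype=float)
    for name, col in (("time", times), ("value", values)):
        bad = np.flatnonzero(~np.isfinite(col))
        if bad.size:
            raise ValidationError(
                f"{path}: missing or non-numeric {name} at data row {bad[0] + 2}"
            )
    diffs = np.diff(times)
    nonmono = np.flatnonzero(diffs <= 0)
    if nonmono.size:
        raise ValidationError(
            f"{path}: time not strictly increasing at data row {nonmono[0] + 3} "
            f"(t={times[nonmono[0] + 1]!r} after t={times[nonmono[0]]!r})"
        )
    dt = float(np.median(diffs))
    dev = np.abs(diffs - dt)
    bad = np.flatnonzero(dev > 1e-6 * dt)
    if bad.size:
        raise ValidationError(
            f"{path}: non-uniform sampling step at data row {bad[0] + 3} "
            f"(step {diffs[bad[0]]:.6g} h, expected {dt:.6g} h)"
        )
    return UniformSeries(
        times=times, values=values, dt_h=dt,
        label=label if label is not None else Path(path).stem,
    )


def write_series(series: UniformSeries, path, dialect: str = "csv") -> None:
    """Write a series as ``time_h,backscatter_au`` delimited text."""
    if dialect not in _SEPARATORS:
        raise ValidationError(f"unknown dialect {dialect!r}; use 'csv' or 'tsv'")
    frame = pd.DataFrame({"time_h": series.times, "backscatter_au": series.values})
    frame.to_csv(path, sep=_SEPARATORS[dialect], index=False)


def read_phospho(path, dialect: str | None = None):
    """Read a ``time_h,rep1,rep2,...`` replicate-ratio table.

    Returns ``(times, ratios)`` with ratios as an (n_times, n_replicates)
    DataFrame.
    """
    frame = _read_table(path, dialect)
    if frame.shape[1] < 2:
        raise ValidationError(f"{path}: need a time column and >= 1 replicate column")
    times = pd.to_numeric(frame.iloc[:, 0], errors="coerce").to_numpy(dtype=float)
    ratios = frame.iloc[:, 1:].apply(pd.to_numeric, errors="coerce")
    if np.any(~np.isfinite(times)):
        bad = int(np.flatnonzero(~np.isfinite(times))[0])
        raise ValidationError(f"{path}: bad time at data row {bad + 2}")
    if ratios.isna().to_numpy().any():
        row = int(np.flatnonzero(ratios.isna().any(axis=1))[0])
        raise ValidationError(f"{path}: missing/non-numeric ratio at data row {row + 2}")
    return times, ratios
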