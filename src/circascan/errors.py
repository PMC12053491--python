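"""Exception hierarchy for circascan.

All package errors derive from :class:`CircascanError` so callers can catch
everything with one clause; the subclasses distinguish bad configuration,
malformed input data, series too short for an operation, and the two
"no result" outcomes (no circadian spectral peak, no usable phase).
"""


class CircascanError(Exception):
    """Base class for all circascan errors."""


class ConfigurationError(CircascanError, ValueError):
    """A parameter value violates its documented constraints."""


class ValidationError(CircascanError, ValueError):
    """Input data violate the contract of an operation (non-uniform grid,
    out-of-range values, mismatched shapes, ...)."""


class InsufficientDataError(CircascanError, ValueError):
    """The series is too short for the requested operation."""


class DegenerateSeriesError(CircascanError, ValueError):
    """The series has (numerically) zero variance where variability is required."""


class NoCircadianPeakError(CircascanError):
    """No spectral peak fell inside the circadian plausibility band.

    The full ranked peak list is attached as ``.peaks`` — a list of
    ``(frequency_per_h, period_h, magnitude, rank)`` tuples — so callers can
    inspect what *was* found.
    """

    def __init__(self, message: str, peaks=None):
        super().__init__(message)
        self.peaks = list(peaks) if peaks is not None else []


class NoPhaseError(CircascanError):
    """Phase comparison impossible because a series has no detected peaks."""
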