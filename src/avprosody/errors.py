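"""Exception hierarchy for the avprosody pipeline.

All pipeline-specific failures derive from :class:`AVProsodyError` so callers
can distinguish data/configuration problems from programming errors.
"""


class AVProsodyError(Exception):
    """Base class for all avprosody errors."""


class SchemaError(AVProsodyError):
    """A required column is absent (after applying any column map)."""


class DuplicateRecordError(AVProsodyError):
    """More than one record for the same (episode, frame, speaker)."""


class EmptyInputError(AVProsodyError):
    """An operation received an empty collection where data is required."""


class SrtParseError(AVProsodyError):
    """A SubRip file violates the format; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class InvalidIntervalError(AVProsodyError):
    """A subtitle interval has end <= start."""


class PositionRangeError(AVProsodyError):
    """A window position lies outside [-60, 60]."""


class FormatError(AVProsodyError):
    """A table's orientation (wide/long) could not be determined."""


class DegenerateFaceError(AVProsodyError):
    """Landmark geometry is degenerate (zero normalizing distance, collinear axes)."""


class ZeroVarianceError(AVProsodyError):
    """A speaker's measurements are constant; z-scoring is undefined."""


class OverlapError(AVProsodyError):
    """Two subtitle segments of the same episode overlap."""


class NoPeakError(AVProsodyError):
    """A segment has no non-missing eyebrow value to locate a peak in."""


class InsufficientDataError(AVProsodyError):
    """Too few observations for the requested operation."""


class UnidentifiableFrequencyError(AVProsodyError):
    """f = 0 makes the sinusoid's phase/amplitude non-unique."""


class UndefinedRSquaredError(AVProsodyError):
    """Total sum of squares is zero; r-squared is undefined."""


class PhaseRangeError(AVProsodyError):
    """phi outside [0, 2); normalize parameters first."""


class BasisError(AVProsodyError):
    """Smoother basis size exceeds the available distinct positions."""


class DegenerateGroupingError(AVProsodyError):
    """Mixed model requested with fewer than two grouping levels."""


class CollinearityError(AVProsodyError):
    """Predictor matrix is rank-deficient."""


class NoOverlapError(AVProsodyError):
    """Inner join of pre and post fit tables is empty."""


class ConfigError(AVProsodyError):
    """Invalid configuration value."""


class MissingArtifactError(AVProsodyError):
    """A report was requested from an incomplete pipeline bundle."""
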