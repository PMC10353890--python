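"""Exception hierarchy shared across the pipeline stages."""


class FlyCourtError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(FlyCourtError, ValueError):
    """A configuration value violates its documented constraint."""


class GeometryError(FlyCourtError, ValueError):
    """Image or arena geometry is inconsistent (e.g. frame smaller than ROI)."""


class CalibrationError(FlyCourtError, RuntimeError):
    """Spatial calibration failed (no arena circle found)."""


class AlignmentError(FlyCourtError, ValueError):
    """Two time series that must share a frame axis do not."""


class EmptyInputError(FlyCourtError, ValueError):
    """An operation received no frames / no data."""


class RangeError(FlyCourtError, ValueError):
    """Event times fall outside the recording span."""


class ParseError(FlyCourtError, ValueError):
    """A file could not be parsed; the message names the offending column."""


class InsufficientReplicatesError(FlyCourtError, ValueError):
    """A statistical comparison was requested with too few replicates."""


class InsufficientLevelsError(FlyCourtError, ValueError):
    """A dose-response summary needs at least three intensity levels."""


class DegenerateInputError(FlyCourtError, ValueError):
    """Input is degenerate for the requested operation (e.g. all-zero spectrum)."""


class OverlapError(FlyCourtError, ValueError):
    """Song elements to synthesize overlap in time."""


class SampleRateError(FlyCourtError, ValueError):
    """Audio sample rate is too low for the requested analysis band."""
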