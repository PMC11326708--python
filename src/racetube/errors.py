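"""Exception hierarchy for the race-tube analysis pipeline."""


class RaceTubeError(Exception):
    """Base class for all package-specific errors."""


class ImageFormatError(RaceTubeError):
    """The input file is missing, unreadable, or not a supported raster format."""


class DegenerateInputError(RaceTubeError):
    """The input is structurally valid but empty or zero-area."""


class ConfigError(RaceTubeError):
    """A parameter combination is invalid (e.g. smoothing window <= polynomial order)."""


class NoTubesError(RaceTubeError):
    """Boundary selection left fewer than two tube regions."""


class CalibrationError(RaceTubeError):
    """Time marks are insufficient or mis-ordered for a pixel<->hour calibration."""


class InsufficientPeaksError(RaceTubeError):
    """Fewer than two conidial band peaks in the analysis window."""


class DegenerateSeriesError(RaceTubeError):
    """A periodogram was requested for a zero-variance (constant) series."""


class WindowError(RaceTubeError):
    """Invalid analysis window (mark indices out of order or out of range)."""


class SelectionError(RaceTubeError):
    """Invalid selection for summary statistics (empty, or mixed methods)."""


class SchemaError(RaceTubeError):
    """Experiment file has an unknown or incompatible schema version."""


class ResolutionError(RaceTubeError):
    """Synthetic band spacing too small to be resolvable at image resolution."""
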