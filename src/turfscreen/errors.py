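"""Exception hierarchy shared across the pipeline stages."""


class TurfscreenError(Exception):
    """Base class for all package errors."""


class ConfigError(TurfscreenError):
    """Invalid configuration or mismatched inputs (exit code 2 in the CLI)."""


class DataError(TurfscreenError):
    """Invalid or degenerate data encountered at run time (exit code 3)."""


class GeometryError(ConfigError):
    """A rectangle or shift does not fit the raster it is applied to."""


class InvalidParameterError(ConfigError):
    """A numeric parameter violates its documented domain."""


class InsufficientPanelsError(DataError):
    """Fewer than two spectrally distinct calibration panels were supplied."""


class DegenerateInputError(DataError):
    """Input has no usable structure (e.g. all pixel values identical)."""


class UndefinedStatisticError(DataError):
    """A statistic is undefined for the given sample (e.g. zero variance)."""
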