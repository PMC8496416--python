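"""Exception hierarchy shared across the package."""


class OknError(Exception):
    """Base class for all package-specific errors."""


class FormatError(OknError):
    """A file does not conform to the expected layout (e.g. missing column)."""


class DataError(OknError):
    """Content-level problem in otherwise well-formed input (e.g. non-monotone time)."""


class ConfigError(OknError):
    """Invalid configuration value or combination."""


class InsufficientDataError(OknError):
    """Not enough samples/points to run the requested operation."""


class NoiseEstimationError(OknError):
    """The velocity-noise window contains too few usable samples."""
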