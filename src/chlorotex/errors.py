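"""Exception hierarchy.

``DataError`` covers problems with the data handed to a stage (maps to CLI
exit code 1); ``ConfigError`` covers invalid parameterization (exit code 2).
"""


class ChlorotexError(Exception):
    """Base class for all package errors."""


class ConfigError(ChlorotexError, ValueError):
    """Invalid configuration values."""


class SceneConfigError(ConfigError):
    """Scene cannot be generated under the requested configuration."""


class DataError(ChlorotexError, ValueError):
    """Invalid or inconsistent input data."""


class FormatError(DataError):
    """A file does not conform to the expected on-disk format."""


class BandLookupError(DataError):
    """A requested wavelength is outside the cube's spectral range."""


class EmptyROIError(DataError):
    """A region of interest retains no usable pixels after masking."""


class RegistryError(DataError, KeyError):
    """Unknown feature or model name."""


class UndefinedCorrelationError(DataError):
    """Correlation is undefined (constant input)."""


class RankError(DataError):
    """Degenerate covariance; PCA cannot be computed."""
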