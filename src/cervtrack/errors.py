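"""Exception hierarchy.

``ConfigError`` maps to CLI exit code 2, ``DataError`` (and subclasses) to 3.
"""


class CervtrackError(Exception):
    """Base class for all package errors."""


class ConfigError(CervtrackError):
    """Invalid configuration or unusable parameter combination."""


class DataError(CervtrackError):
    """Input data violates a contract."""


class DimensionError(DataError):
    """Frames or masks with inconsistent shapes."""


class FormatError(DataError):
    """Unsupported pixel type or on-disk layout."""


class InsufficientDataError(DataError):
    """Fewer frames/observations than the operation requires."""


class DegenerateInputError(DataError):
    """Input with no usable variation (e.g. constant reference image)."""
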