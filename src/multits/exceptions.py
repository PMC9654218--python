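"""Exception hierarchy shared across the package."""


class MultitsError(Exception):
    """Base class for all package-specific errors."""


class FormatError(MultitsError):
    """A file could not be parsed as the expected on-disk format."""


class UnsupportedDialectError(FormatError):
    """The file is recognisable but uses an unsupported variant
    (e.g. an EDF with per-channel sampling rates)."""


class IntegrityError(MultitsError):
    """Stored data does not match its manifest (shape, byte length, checksum)."""


class ConfigError(MultitsError):
    """Invalid configuration value or unknown configuration key."""


class ParameterError(MultitsError, ValueError):
    """An operation was called with out-of-domain parameters."""


class ShapeError(MultitsError, ValueError):
    """Array dimensions are inconsistent with the operation's contract."""


class ConstructionError(MultitsError):
    """A network stage cannot be built (e.g. pooling exhausts the time axis)."""


class EmptyEpochSetError(MultitsError):
    """A recording is too short to yield a single epoch."""


class DegenerateDataError(MultitsError):
    """Input data is degenerate for the requested statistic or fit
    (single-class training labels, zero-variance differences, ...)."""


class SchemeError(MultitsError):
    """A cross-validation scheme cannot be applied to the given data."""
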