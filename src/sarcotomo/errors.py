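"""Exception hierarchy shared across the package."""


class SarcotomoError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(SarcotomoError, ValueError):
    """A spec/parameter value is outside its allowed range."""


class GeometryError(SarcotomoError):
    """Degenerate geometry (coincident axes, zero-length vector, ...)."""


class InputError(SarcotomoError, ValueError):
    """Malformed analysis input (unordered subunits, >2 heads per myosin, ...)."""


class InsufficientDataError(SarcotomoError):
    """Too few observations to compute the requested statistic."""


class FormatError(SarcotomoError):
    """A file could not be parsed as the expected format."""


class SchemaError(FormatError):
    """A table is missing required columns."""


class IntegrityError(FormatError):
    """Cross-table references in a serialized model do not resolve."""
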