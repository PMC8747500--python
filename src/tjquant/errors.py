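"""Exception hierarchy shared across the package."""


class TJQuantError(Exception):
    """Base class for all package-specific errors."""


class FormatError(TJQuantError):
    """A file does not conform to the declared dialect/schema."""


class ParseError(TJQuantError):
    """A cell or record could not be parsed; carries a row number."""

    def __init__(self, message: str, row: int | None = None):
        super().__init__(message)
        self.row = row


class ValidationError(TJQuantError):
    """A domain object violates its invariants."""


class ParameterError(TJQuantError, ValueError):
    """An operation received an out-of-range or inconsistent parameter."""


class GeometryError(TJQuantError):
    """A geometric construction (offset, hull, ...) failed."""


class ConsistencyError(TJQuantError):
    """Two inputs that must describe the same data do not agree."""


class NormalizationError(TJQuantError):
    """A normalization is undefined (e.g. reference mean is zero)."""


class ConfigError(TJQuantError):
    """A configuration object is internally inconsistent."""
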