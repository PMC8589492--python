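"""Exception hierarchy shared across the package."""


class GDYNetError(Exception):
    """Base class for package errors."""


class ConfigurationError(GDYNetError, ValueError):
    """A config object violates its invariants."""


class DomainError(GDYNetError, ValueError):
    """An input value lies outside the mathematical domain of an operation."""


class ShapeError(GDYNetError, ValueError):
    """Array shapes are inconsistent."""


class ValidationError(GDYNetError, ValueError):
    """A manifest, file, or report fails schema validation."""


class LocalizationError(GDYNetError, RuntimeError):
    """The CAM-based localizer produced no usable region of interest."""
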