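"""Exception hierarchy for conescale."""


class ConescaleError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ConescaleError):
    """Invalid configuration value or malformed input structure."""


class DomainError(ConescaleError, ValueError):
    """Argument outside the physically meaningful domain of an operation."""


class GeometryError(ConescaleError):
    """Geometrically invalid cross-section or scale model."""


class CalibrationError(ConescaleError):
    """Inverse solve could not be carried out (bad bracket, non-monotone forward map)."""
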