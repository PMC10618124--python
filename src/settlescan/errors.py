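"""Exception hierarchy used across the pipeline stages."""


class SettlescanError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(SettlescanError, ValueError):
    """A record violates the documented survey schema (unknown code, bad column)."""


class DomainError(SettlescanError, ValueError):
    """An argument is outside the mathematical domain of an operation."""


class ConfigError(SettlescanError, ValueError):
    """A simulation or pipeline configuration is invalid."""


class ParseError(SettlescanError, ValueError):
    """An input file does not conform to the documented CSV/GeoJSON schema."""


class SeparationError(DomainError):
    """A logistic fit is degenerate (constant outcome or perfect separation)."""
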