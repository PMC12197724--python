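"""Error types raised on invalid inputs."""


class SoilRiskError(ValueError):
    """Base class for all package errors."""


class SchemaError(SoilRiskError):
    """A required column or table key is missing or unrecognised."""


class ValidationError(SoilRiskError):
    """Row-level data fails an invariant (non-positive concentration, ...)."""


class DomainError(SoilRiskError):
    """A scalar argument is outside its physical domain."""
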