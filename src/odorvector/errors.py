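"""Exception hierarchy for odorvector."""


class OdorVectorError(Exception):
    """Base class for all odorvector errors."""


class ValidationError(OdorVectorError, ValueError):
    """A record or table violates an invariant (bad threshold, duplicate key, ...)."""


class DomainError(OdorVectorError, ValueError):
    """A numeric argument is outside the mathematical domain of an operation."""


class ConfigurationError(OdorVectorError, ValueError):
    """A model constant or option is invalid (cos alpha outside [-1, 1], unknown model, ...)."""


class UnknownOdorantError(OdorVectorError, KeyError):
    """Lookup of an odorant by abbreviation or CAS number failed."""


class DegenerateFitError(OdorVectorError, ValueError):
    """A regression cannot be performed (too few points, zero design norm)."""
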