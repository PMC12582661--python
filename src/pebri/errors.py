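"""Exception hierarchy for the pebri package."""


class PebriError(Exception):
    """Base class for all pebri errors."""


class DomainError(PebriError, ValueError):
    """A numeric argument is outside the mathematical domain of an operation."""


class DataError(PebriError, ValueError):
    """Input data violates a structural requirement (schema, ordering, size)."""


class ConfigError(PebriError, ValueError):
    """A configuration object violates its invariants."""


class EstimationError(PebriError, RuntimeError):
    """An estimation step cannot produce a usable result from the given data."""
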