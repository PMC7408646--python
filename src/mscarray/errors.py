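"""Exception hierarchy shared across the pipeline stages."""


class MscArrayError(Exception):
    """Base class for all package-specific errors."""


class FormatError(MscArrayError):
    """A file does not conform to the expected dialect (missing column,
    missing table markers, unparseable row)."""


class ConfigError(MscArrayError):
    """A configuration object violates its invariants."""


class ContractError(MscArrayError):
    """An operation was called with inputs that violate its preconditions
    (empty replicate population, mixed probe ids, single pair, ...)."""


class DegenerateArrayError(MscArrayError):
    """An array cannot be normalized: all values missing or the reference
    percentile of the measured signals is zero."""


class NoNetGrowthError(MscArrayError):
    """Cell counts did not increase between passages, so a population
    doubling time is undefined for this culture."""
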