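"""Exception types shared across the package."""


class AdjAucError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(AdjAucError):
    """An input table is missing a required column or has the wrong layout."""


class ConfigError(AdjAucError):
    """A configuration file is malformed or contains unknown keys."""


class InsufficientDataError(AdjAucError):
    """Too few distinct concentrations for the requested fit."""


class NoValueError(AdjAucError):
    """A metric was requested from a fit that cannot support it
    (e.g. a non-converged fit)."""


class IncomparableRangesError(AdjAucError):
    """Concentration ranges do not overlap, so no shared window exists."""


class UndefinedCorrelationError(AdjAucError):
    """Correlation undefined: fewer than three pairs or zero variance."""
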