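"""Typed exceptions shared across the package."""


class TempomodError(Exception):
    """Base class for all package errors."""


class ParseError(TempomodError):
    """A file could not be tokenized into the expected tabular layout."""


class SchemaError(TempomodError):
    """A file parsed, but its columns/ids do not match the declared schema."""


class ValidationError(TempomodError):
    """Values violate an invariant (negative count, duplicate id, ...)."""


class DesignError(TempomodError):
    """The experimental design is incomplete or too small for the analysis."""


class ConfigurationError(TempomodError):
    """Mutually inconsistent or infeasible parameters."""


class UndefinedStatisticError(TempomodError):
    """A requested statistic has no defined value (zero denominator etc.)."""
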