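"""Exception hierarchy for the carpfrost pipeline.

Every error raised on purpose derives from :class:`CarpfrostError`, so callers
(and the CLI exit-code mapping) can distinguish configuration problems, data
problems and numerical problems from genuine bugs.
"""


class CarpfrostError(Exception):
    """Base class for all carpfrost errors."""


class ConfigError(CarpfrostError):
    """Invalid or contradictory configuration."""


class DataError(CarpfrostError):
    """Base class for problems with input data."""


class SchemaError(DataError):
    """A required column is missing from a CSV file."""


class UniquenessError(DataError):
    """Duplicate (temperature, time, indicator, replicate) key."""


class ValidationError(DataError):
    """A row violates a domain invariant (negative time/value, unknown name)."""


class BaselineMissingError(DataError):
    """No time-0 record for a (temperature, indicator) under require_t0."""


class NoCompleteRowsError(DataError):
    """No (temperature, time) point carries all five indicator deltas."""


class InsufficientDataError(DataError):
    """Too few rows for the requested operation."""


class DegenerateVariableError(DataError):
    """A variable is constant, so min-max scaling is undefined."""


class InfeasibleAnchorError(DataError):
    """Anchor values incompatible with a monotone exponential trajectory."""


class NumericalError(CarpfrostError):
    """Base class for numerical-state problems."""


class DimensionError(NumericalError):
    """Array shapes do not match the network's arity."""


class ModelStateError(NumericalError):
    """Operation requires a trained network."""


class ModelParseError(CarpfrostError):
    """A saved model file is malformed; the message names the offending field."""


class UndefinedValueError(NumericalError):
    """A quantity is undefined for the given input (e.g. relative error at 0)."""
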