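"""Exception hierarchy.

Graph construction, conditional-independence testing, parameter fitting,
prediction and I/O each raise narrowly-typed errors so that callers (and the
learning loops, which must stay total) can distinguish recoverable
degeneracies from genuine misuse.
"""


class AmenbnError(Exception):
    """Base class for all package errors."""


class CycleError(AmenbnError):
    """Adding an arrow would create a directed cycle."""


class IllegalArrowError(AmenbnError):
    """Arrow violates CLG legality (continuous parent of a discrete child)."""


class IllegalGraphError(AmenbnError):
    """A whole DAG violates CLG legality or references unknown variables."""


class NotDiscreteError(AmenbnError):
    """A discrete-only test was handed a continuous variable."""


class NotContinuousError(AmenbnError):
    """A continuous-only operation was handed a discrete variable."""


class DegenerateError(AmenbnError):
    """A statistic is undefined because a variable is constant/degenerate."""


class InsufficientDataError(AmenbnError):
    """Too few rows to carry out the requested fit or test."""


class EmptyConfigError(AmenbnError):
    """A discrete-parent configuration has no rows; recorded, not fatal."""


class NoEquationError(AmenbnError):
    """No prediction equation matches the record's discrete configuration."""


class MissingCovariateError(AmenbnError):
    """A required continuous covariate is absent from the record."""


class LengthMismatchError(AmenbnError):
    """Paired vectors (predicted/observed) differ in length."""


class ConfigError(AmenbnError):
    """Invalid generator configuration (probabilities, bounds, sizes)."""


class SchemaError(AmenbnError):
    """Dataset violates the CSV schema (named column/row in the message)."""


class ParseError(AmenbnError):
    """A cell failed to parse; message carries the line number."""
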