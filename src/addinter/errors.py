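"""Typed exceptions shared across the package."""


class AddinterError(Exception):
    """Base class for all package errors."""


class ValidationError(AddinterError, ValueError):
    """A field or row failed validation; the message names the field."""


class SchemaError(AddinterError, ValueError):
    """Input file is missing required columns or is otherwise unreadable."""


class ZeroCellError(AddinterError, ValueError):
    """A contingency cell is zero and no continuity correction was requested."""


class UndefinedMeasureError(AddinterError, ArithmeticError):
    """An interaction measure is undefined at the given odds ratios
    (e.g. synergy index with non-positive denominator, PAP with OR11 <= 1)."""


class ConvergenceError(AddinterError, RuntimeError):
    """Model fitting failed to converge (separation, rank deficiency...)."""


class MatchingError(AddinterError, RuntimeError):
    """Matched-control sampling could not reach the requested number of pairs."""

    def __init__(self, message: str, achievable_pairs: int = 0):
        super().__init__(message)
        self.achievable_pairs = achievable_pairs
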