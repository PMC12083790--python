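"""Exception hierarchy shared across the package.

Every error raised by the library derives from :class:`SepselectError` so CLI
and pipeline code can catch one type and tag it with the failing stage.
"""


class SepselectError(Exception):
    """Base class for all sepselect errors."""


class StructuralError(SepselectError, ValueError):
    """The shape or schema of an input is wrong (missing column, duplicate id...)."""


class DataParseError(SepselectError, ValueError):
    """A cell of an input file could not be parsed; the message names row/column."""


class DomainError(SepselectError, ValueError):
    """An argument is outside the mathematical domain of an operation."""


class NumericError(SepselectError, ArithmeticError):
    """A computation produced or received non-finite values."""


class ShapeError(SepselectError, ValueError):
    """A matrix does not match the feature geometry a fitted model expects."""
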