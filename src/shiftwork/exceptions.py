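"""Exception hierarchy shared across the package.

Everything derives from :class:`ShiftworkError` so callers can catch one base;
most classes also derive from ``ValueError`` to behave sanely in generic code.
"""


class ShiftworkError(Exception):
    """Base class for all errors raised by this package."""


class ParameterError(ShiftworkError, ValueError):
    """An argument is outside its documented domain (e.g. run length < 1)."""


class EmptyInputError(ShiftworkError, ValueError):
    """An operation received an empty series or vector."""


class DegenerateInputError(ShiftworkError, ValueError):
    """Input is formally valid but the statistic is undefined on it
    (e.g. no wake epochs when classifying quiet wakefulness)."""


class UndefinedStatisticError(ShiftworkError, ValueError):
    """A test statistic has a zero denominator with a nonzero numerator."""


class MissingReferenceError(ShiftworkError, KeyError):
    """Baseline normalization lacks a (state, circadian-bin) reference cell.

    ``cells`` lists the missing (state, bin-start-hour) pairs.
    """

    def __init__(self, cells):
        self.cells = list(cells)
        super().__init__(
            "missing baseline reference cell(s): "
            + ", ".join(f"(state={s!r}, zt_bin=[{b:g}h,...))" for s, b in self.cells)
        )


class CollinearityError(ShiftworkError, ValueError):
    """Design matrix is rank deficient. ``columns`` names the offending columns."""

    def __init__(self, columns, message=None):
        self.columns = list(columns)
        super().__init__(
            message or f"collinear predictor column(s): {', '.join(map(str, self.columns))}"
        )


class InsufficientDataError(ShiftworkError, ValueError):
    """Too few observations for the number of parameters requested."""
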