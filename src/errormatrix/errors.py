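"""Exception hierarchy for the error-matrix package.

Errors are split into data errors (a particular study/outcome cell cannot
yield the requested quantity) and usage errors (invalid arguments, files or
configuration). Data errors carry enough context to be reported per row.
"""


class ErrorMatrixError(Exception):
    """Base class for all package errors."""


class ZeroEventError(ErrorMatrixError):
    """An effect measure or SE is undefined because an arm (or both) has
    zero events. Carries the missingness code ``Z``."""

    code = "Z"


class DegenerateTableError(ErrorMatrixError):
    """A 2x2 table is structurally unable to support the requested measure
    (e.g. no non-events anywhere, or fewer than two patients)."""


class NullEffectError(ErrorMatrixError):
    """Absolute risk difference is zero, so the NNT is undefined."""


class NoEventsError(ErrorMatrixError):
    """A pooled estimate is undefined because no trial contributes events."""


class DomainError(ErrorMatrixError):
    """An argument is outside the mathematical domain of an operation."""


class UnknownLevelError(ErrorMatrixError):
    """An evidence-level label is not one of the ten recognised labels."""

    def __init__(self, label, valid):
        self.label = label
        self.valid = tuple(valid)
        super().__init__(
            f"unknown evidence level {label!r}; valid labels: {', '.join(self.valid)}"
        )


class NoEvidenceError(ErrorMatrixError):
    """No study record has a computable standard error for an outcome."""


class UnknownFixtureError(ErrorMatrixError):
    """Requested packaged fixture does not exist."""


class SchemaError(ErrorMatrixError):
    """A study-table file violates the input schema.

    Attributes ``row`` (1-based data row number, or None) and ``column``
    locate the offending value when known.
    """

    def __init__(self, message, row=None, column=None):
        self.row = row
        self.column = column
        where = ""
        if row is not None:
            where += f" (row {row}"
            where += f", column {column!r})" if column is not None else ")"
        super().__init__(message + where)


class ConfigError(ErrorMatrixError):
    """Invalid synthetic-trial or analysis configuration."""


class RenderError(ErrorMatrixError):
    """A figure could not be written."""
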