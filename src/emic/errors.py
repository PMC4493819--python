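"""Exception hierarchy shared across the package."""

from __future__ import annotations


class EmicError(Exception):
    """Base class for all package errors."""


class InputDomainError(EmicError, ValueError):
    """An argument is outside its mathematical domain (q outside [0,1],
    pYLD >= 1, negative cost or discount rate, age outside the table)."""


class ConfigurationError(EmicError, ValueError):
    """Inconsistent configuration: mismatched base years, last-year-of-life
    multipliers without a decedent cost schedule, mismatched schedule lengths."""


class UnsupportedFeatureError(EmicError, NotImplementedError):
    """A documented extension point that is not implemented (multi-year
    risk duration)."""


class InputValidationError(EmicError, ValueError):
    """A delimited input file failed validation.

    Carries enough context to name the offending file, column and row in the
    message, so command-line users can fix the file without reading a trace.
    """

    def __init__(self, message: str, *, source: str | None = None,
                 column: str | None = None, row: int | None = None) -> None:
        where = []
        if source is not None:
            where.append(f"file {source!r}")
        if column is not None:
            where.append(f"column {column!r}")
        if row is not None:
            where.append(f"row {row}")
        full = message if not where else f"{message} ({', '.join(where)})"
        super().__init__(full)
        self.source = source
        self.column = column
        self.row = row
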