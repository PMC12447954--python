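"""Exception hierarchy shared across the package."""


class PaleoneuroError(Exception):
    """Base class for all package errors."""


class DomainError(PaleoneuroError, ValueError):
    """An input value is outside the operation's domain (e.g. nonpositive mass)."""


class SchemaError(PaleoneuroError, ValueError):
    """A table header does not match the expected column schema."""


class TableParseError(PaleoneuroError, ValueError):
    """A cell could not be parsed; carries the offending row and column."""

    def __init__(self, message: str, row: int | None = None, column: str | None = None):
        super().__init__(message)
        self.row = row
        self.column = column


class DegenerateFitError(DomainError):
    """A regression cannot be fitted (too few or degenerate points)."""


class DegenerateGeometryError(DomainError):
    """A convex polygon cannot be built (fewer than 3 points, or all collinear)."""


class ConfigError(PaleoneuroError, ValueError):
    """A synthetic-data configuration field is invalid; names the field."""

    def __init__(self, field: str, message: str):
        super().__init__(f"{field}: {message}")
        self.field = field


class StateError(PaleoneuroError, RuntimeError):
    """An object is used before being put into the required state."""
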