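"""Exception hierarchy shared across the package."""


class PTMLError(Exception):
    """Base class for all package errors."""


class SchemaError(PTMLError):
    """A file or table does not match the expected schema."""


class RowParseError(PTMLError):
    """A specific row could not be parsed."""

    def __init__(self, row: int, message: str):
        self.row = row
        super().__init__(f"row {row}: {message}")


class SurfParseError(PTMLError):
    """A SURF record line is malformed."""

    def __init__(self, record_index: int, message: str):
        self.record_index = record_index
        super().__init__(f"SURF record {record_index}: {message}")


class ValidationError(PTMLError):
    """A domain invariant is violated."""


class DomainError(PTMLError):
    """An argument is outside its mathematical domain."""


class KeyingError(PTMLError):
    """A record is missing a condition variable needed for grouping."""


class RecipeError(PTMLError):
    """A feature-recipe term cannot be resolved against the tables."""


class ReferenceError_(PTMLError):
    """A record's conditioning group has no observed yields."""


class SingularityError(PTMLError):
    """The regression design matrix is rank deficient."""

    def __init__(self, collinear: list[str]):
        self.collinear = list(collinear)
        super().__init__(
            "rank-deficient design; collinear columns: " + ", ".join(self.collinear)
        )


class ContractError(PTMLError):
    """Model and feature table disagree (missing column etc.)."""


class ImputationError(PTMLError):
    """No ladder level could supply a value for a missing field."""

    def __init__(self, rows, message: str):
        self.rows = list(rows)
        super().__init__(message)


class ConfigError(PTMLError):
    """Invalid configuration."""
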