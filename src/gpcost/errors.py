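"""Exception hierarchy: schema errors (wrong columns) vs row-level validation."""


class GpcostError(Exception):
    """Base class for all package errors."""


class SchemaError(GpcostError):
    """A required column is missing or a config key is malformed."""


class ValidationError(GpcostError):
    """A row violates a domain invariant; carries the offending row number."""

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        if row is not None:
            message = f"row {row}: {message}"
        super().__init__(message)
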