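"""Exception hierarchy for the harmonization pipeline.

Every error names the offending file/column/token so that a failed build can
be traced back to a single census cell.
"""


class AfaError(Exception):
    """Base class for all package errors."""


class VocabularyError(AfaError):
    """An invasion-status token is not a member of the unified vocabulary."""

    def __init__(self, token: str, context: str = ""):
        self.token = token
        msg = f"unknown invasion-status token {token!r}"
        if context:
            msg += f" ({context})"
        super().__init__(msg)


class InputError(AfaError):
    """Invalid caller-supplied value (empty list, empty name, bad rate)."""


class ParseError(AfaError):
    """Malformed packed distribution string; carries the character offset."""

    def __init__(self, message: str, offset: int | None = None):
        self.offset = offset
        if offset is not None:
            message = f"{message} (at offset {offset})"
        super().__init__(message)


class SchemaError(AfaError):
    """A table is missing a column the conversion rules require."""

    def __init__(self, census_id: str, column: str):
        self.census_id = census_id
        self.column = column
        super().__init__(
            f"census {census_id!r}: required column {column!r} is missing"
        )


class ConfigError(AfaError):
    """Malformed rule set, dialect or run configuration."""
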