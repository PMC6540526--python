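"""Exception hierarchy shared across the package."""


class RepclonityError(Exception):
    """Base class for all package errors."""


class FormatError(RepclonityError):
    """A file does not conform to the expected tabular/FASTA format."""


class RecordError(RepclonityError):
    """A single record is invalid (carries the offending row number)."""

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        if row is not None:
            message = f"row {row}: {message}"
        super().__init__(message)


class EmptyRepertoireError(RepclonityError):
    """An operation requiring at least one counted clone got none."""
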