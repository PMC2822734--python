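"""Exception hierarchy shared across the package."""


class PhenoshareError(Exception):
    """Base class for all package-specific errors."""


class FormatError(PhenoshareError, ValueError):
    """A file does not conform to the expected format.

    Raised for missing mandatory columns, malformed stanzas, row/count
    mismatches and duplicate labels in on-disk inputs.
    """


class RecordParseError(FormatError):
    """A single data row could not be parsed; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int | None = None):
        super().__init__(message)
        self.line_number = line_number


class PreconditionError(PhenoshareError, ValueError):
    """An operation received input violating its documented contract."""
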