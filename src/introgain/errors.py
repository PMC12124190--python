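"""Exception hierarchy for the intron-gain pipeline."""


class IntrogainError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(IntrogainError, ValueError):
    """A simulation or pipeline configuration violates its invariants."""


class MalformedModelError(IntrogainError, ValueError):
    """A gene model violates a structural invariant (e.g. CDS length % 3)."""


class OutOfRangeError(IntrogainError, ValueError):
    """A coordinate falls outside the sequence it refers to."""


class NotFoundError(IntrogainError, KeyError):
    """A requested species/accession/ordinal is absent."""


class TableParseError(IntrogainError, ValueError):
    """A tabular input file could not be parsed; carries the line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class ConsistencyError(IntrogainError, ValueError):
    """Imported data disagrees with the in-memory objects it should match."""
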