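"""Exception hierarchy shared across the pipeline."""


class NetpharmError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(NetpharmError, ValueError):
    """A value violates a domain invariant (empty symbol, infeasible counts...)."""


class FormatError(NetpharmError, ValueError):
    """A file does not conform to the expected delimited-text layout.

    ``line`` is the 1-based line number of the offending row when known;
    ``column`` names a missing or malformed column when that is the cause.
    """

    def __init__(self, message: str, *, line: int | None = None, column: str | None = None):
        self.line = line
        self.column = column
        prefix = []
        if column is not None:
            prefix.append(f"column {column!r}")
        if line is not None:
            prefix.append(f"line {line}")
        if prefix:
            message = f"{message} ({', '.join(prefix)})"
        super().__init__(message)
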