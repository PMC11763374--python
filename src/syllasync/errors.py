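"""Exception hierarchy shared across the package."""


class SyllasyncError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(SyllasyncError, ValueError):
    """Malformed or inconsistent user input (bad sequences, windows, files)."""


class DomainError(SyllasyncError, ValueError):
    """A numeric argument outside its mathematical domain (e.g. rate <= 0)."""


class DimensionConflictError(SyllasyncError, ValueError):
    """Two simultaneous gestures demand the same dimension with no sequential split."""

    def __init__(self, dimension: str, message: str | None = None):
        self.dimension = dimension
        super().__init__(message or f"conflicting simultaneous demands on dimension {dimension!r}")


class OracleFailureError(SyllasyncError, RuntimeError):
    """The reference integrator failed to converge; tests must abort, never pass."""


class ParseError(SyllasyncError, ValueError):
    """A file could not be parsed; carries a line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class FitError(SyllasyncError, RuntimeError):
    """All optimizer starts failed to converge."""
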