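"""Exception hierarchy shared across the package."""


class DrivernetError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(DrivernetError, ValueError):
    """An invalid parameter value; the message names the offending field."""


class DegenerateInputError(DrivernetError, ValueError):
    """Input is formally valid but statistically degenerate (e.g. zero variance)."""


class FormatError(DrivernetError, ValueError):
    """A file does not conform to the expected tabular dialect."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class ConvergenceError(DrivernetError, RuntimeError):
    """An iterative solver failed to converge within its iteration budget."""
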