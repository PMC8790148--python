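"""Exception types shared across the toolkit."""


class CyanophageError(Exception):
    """Base class for all toolkit errors."""


class FormatError(CyanophageError):
    """A file violates its declared format; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class ArgumentError(CyanophageError, ValueError):
    """An argument violates an operation's preconditions."""


class UndefinedValueError(CyanophageError, ArithmeticError):
    """A requested quantity is mathematically undefined for this input."""


class NoBurstError(CyanophageError):
    """No sustained rise in free-phage abundance was detected."""


class ConfigError(CyanophageError):
    """A run configuration is invalid or references missing inputs."""
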