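"""Structured exception hierarchy for the pipeline.

Validation problems (bad configs, malformed files, schema violations) are
kept distinct from runtime/numerical problems so the CLI can map them to
exit codes 1 and 2 respectively.
"""


class CatsError(Exception):
    """Base class for all package errors."""


class ValidationError(CatsError):
    """Invalid configuration, schema violation, or malformed input."""


class ConfigError(ValidationError):
    """A configuration field violates its documented constraint."""


class ParseError(ValidationError):
    """A file could not be parsed; carries a line number when known."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class SchemaError(ValidationError):
    """Required columns absent or of the wrong kind."""


class DomainError(CatsError):
    """An operation was called outside its mathematical domain."""


class ConvergenceError(CatsError):
    """An iterative fit failed to converge; carries the iteration trace."""

    def __init__(self, message: str, trace=None):
        super().__init__(message)
        self.trace = trace


class SeparationError(CatsError):
    """Perfect separation detected in a logistic design."""
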