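"""Exception hierarchy for resosharp.

All exceptions derive from :class:`ResosharpError` so callers can catch
library failures with a single except clause; the subclasses distinguish
user-facing error categories (bad input data, incompatible traces,
degenerate intermediate signals, configuration mistakes).
"""

from __future__ import annotations


class ResosharpError(Exception):
    """Base class for all resosharp errors."""


class InvalidInputError(ResosharpError, ValueError):
    """Raised when input data violate an operation's preconditions."""


class IncompatibleTracesError(InvalidInputError):
    """Raised when traces that must share a frequency grid do not."""


class EndpointOrderError(InvalidInputError):
    """Raised when a trace has RL(fmin) > RL(fMAX).

    The preprocessing chain assumes the left band edge sits below the
    right one; callers should frequency-mirror the trace, process it,
    and un-mirror the resulting estimate (``estimate`` does this
    automatically).
    """


class DegenerateSupportError(ResosharpError):
    """Raised when a time support contains fewer than two samples."""


class DegenerateSignalError(ResosharpError):
    """Raised when a signal is identically zero where a peak is required."""


class ConfigurationError(ResosharpError):
    """Raised for unknown algorithm tags or malformed run configuration."""


class ParseError(InvalidInputError):
    """Raised when a trace file cannot be parsed; carries the line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)
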