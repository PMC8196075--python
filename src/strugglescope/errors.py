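"""Exception hierarchy.

All errors raised by the package derive from :class:`StruggleScopeError`,
so callers can catch one type. Subclasses distinguish configuration,
file-format, and numerical/degenerate-input failures (the CLI maps them to
distinct exit codes).
"""


class StruggleScopeError(Exception):
    """Base class for all package errors."""


class ConfigError(StruggleScopeError):
    """Invalid or inconsistent configuration values."""


class FormatError(StruggleScopeError):
    """Malformed input file (bad dialect, non-monotonic index, ...)."""


class MissingPointError(StruggleScopeError):
    """A requested body point is absent from a pose table."""


class InsufficientDataError(StruggleScopeError):
    """Too few samples/frames for the requested operation."""


class DegenerateInputError(StruggleScopeError):
    """Input with no usable variation (zero variance, empty subset, ...)."""


class DomainError(StruggleScopeError):
    """Values outside the mathematical domain of an operation."""
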