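"""Exception hierarchy shared across the package."""


class GradprofError(Exception):
    """Base class for all package-specific errors."""


class ParseError(GradprofError):
    """A file could not be parsed; the message names the offending row/column."""


class ValidationError(GradprofError):
    """An input violated a documented precondition or invariant."""


class UndefinedCorrelationError(ValidationError):
    """Pearson correlation requested for a constant (zero-variance) vector."""


class EmptyResultError(GradprofError):
    """An operation filtered away every record it was given."""
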