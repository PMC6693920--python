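"""Package-specific exception types."""


class BddmError(Exception):
    """Base class for all package errors."""


class DialectError(BddmError, ValueError):
    """A trial CSV does not match the requested dialect (wrong column count)."""


class ParseError(BddmError, ValueError):
    """A trial CSV row could not be parsed; the message names the row."""


class DegenerateInputError(BddmError, ValueError):
    """Input is degenerate for the requested computation (e.g. constant ratings)."""


class SolverAccuracyError(BddmError, RuntimeError):
    """The first-passage solver failed to conserve probability mass at the
    configured grid resolution."""


class OptimizationError(BddmError, RuntimeError):
    """All optimization starts failed to produce a finite objective."""
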