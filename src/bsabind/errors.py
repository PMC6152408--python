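"""Exception hierarchy.

``ValidationError`` covers bad inputs (CLI exit code 2), ``FitError``
covers regressions that cannot be performed (CLI exit code 3).
"""


class BsabindError(Exception):
    """Base class for all package errors."""


class ValidationError(BsabindError, ValueError):
    """Input violates a documented precondition or invariant."""


class ParseError(ValidationError):
    """Malformed text input; the message names the offending line."""


class RangeError(ValidationError):
    """A wavelength or grid falls outside the available data range."""


class FitError(BsabindError, RuntimeError):
    """A regression has too few usable points or is degenerate."""
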