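"""Exception hierarchy shared across the package.

``ValidationError`` (exit code 2 in the CLI) covers malformed or
insufficient input; ``FittingError`` (exit code 3) covers model fits that
cannot be completed.
"""


class Hi3Error(Exception):
    """Base class for all package-specific errors."""


class ValidationError(Hi3Error, ValueError):
    """Input data violates a documented precondition or schema."""


class InsufficientDataError(ValidationError):
    """A series or cohort is too short for the requested computation."""


class UndefinedEntropyError(Hi3Error, ArithmeticError):
    """Sample entropy is undefined because no template matches were found.

    Raised instead of returning a silent sentinel; the caller decides
    whether to exclude the subject.
    """


class FittingError(Hi3Error, RuntimeError):
    """A survival-model fit failed (separation, non-convergence, no events)."""
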