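"""Exception hierarchy shared across the package."""


class StromspatError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(StromspatError, ValueError):
    """A spec or function parameter is outside its valid domain."""


class DegenerateInputError(StromspatError, ValueError):
    """Input is formally valid but carries no usable signal (e.g. constant image)."""


class UndefinedResultError(StromspatError, ArithmeticError):
    """The requested quantity is undefined for this input (e.g. 0/0 fraction).

    Raised instead of silently returning 0, which would be a different claim.
    """


class NoSurfaceError(StromspatError, RuntimeError):
    """No mat surface can be delineated (entirely empty foreground)."""
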