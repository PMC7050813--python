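"""Exception hierarchy shared across the package."""


class StatForensicsError(Exception):
    """Base class for all package errors."""


class InvalidInputError(StatForensicsError, ValueError):
    """An input value violates a precondition (nonpositive n, bad precision, ...)."""


class ShapeError(InvalidInputError):
    """Reported degrees of freedom do not match the stated design shape."""


class CapacityError(StatForensicsError, RuntimeError):
    """An exhaustive enumeration was refused because it would be too large."""


class ParseError(StatForensicsError, ValueError):
    """A statistic string or fixture file could not be parsed."""
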