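"""Exception hierarchy shared across the package."""


class SizeVarPartError(Exception):
    """Base class for all package-specific errors."""


class FormatError(SizeVarPartError):
    """A delimited-text input does not have the expected layout."""


class ValidationError(SizeVarPartError):
    """An input violates a domain invariant (negative counts, bad edges, ...)."""


class DegenerateInputError(SizeVarPartError):
    """Input is structurally valid but carries no usable signal
    (zero-total rows, zero-variance response, ...)."""


class InsufficientDataError(SizeVarPartError):
    """Too few aligned years (or stocks) to run the requested analysis."""


class CollinearityError(SizeVarPartError):
    """A design matrix is rank deficient where full rank is required."""


class SimulationError(SizeVarPartError):
    """The synthetic population collapsed or produced unusable output."""
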