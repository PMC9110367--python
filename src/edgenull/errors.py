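"""Exception hierarchy shared across the package."""


class EdgeNullError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(EdgeNullError, ValueError):
    """An input violates a documented precondition (shape, range, consistency)."""


class DegenerateSignalError(EdgeNullError, ValueError):
    """A node time series is constant (zero variance), so it cannot be z-scored."""


class DegenerateEdgeError(EdgeNullError, ValueError):
    """An edge time series is identically zero, so it cannot be normalised."""


class NumericalError(EdgeNullError, RuntimeError):
    """A numerical routine failed to converge to the requested tolerance."""
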