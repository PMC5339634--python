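"""Exception types shared across the package."""


class ParadetectError(Exception):
    """Base class for all package-specific errors."""


class DegenerateTripletError(ParadetectError):
    """Raised when three points do not determine a parabola.

    This happens when two of the quadratic-argument coordinates coincide
    (the interpolation denominator vanishes) or when the unique interpolating
    polynomial is a line (quadratic coefficient indistinguishable from zero).
    """


class EmptyImageError(ParadetectError):
    """Raised when an edge image has fewer than three foreground pixels."""


class RetryExhaustedError(ParadetectError):
    """Raised when random scene generation cannot place a usable curve."""
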