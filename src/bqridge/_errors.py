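"""Exception hierarchy shared across the package."""


class BqridgeError(Exception):
    """Base class for all package-specific errors."""


class InvalidDataError(BqridgeError):
    """Input data violate a structural requirement (shape, finiteness, missing values)."""


class SingularityError(BqridgeError):
    """An eigenvalue of X'X is numerically zero where a positive one is required."""


class DegenerateCoefficientError(BqridgeError):
    """A ridge-parameter rule hit a zero (or numerically zero) denominator."""


class DegreesOfFreedomError(BqridgeError):
    """n <= p: the residual mean square is undefined."""


class UnstableBootstrapError(BqridgeError):
    """Too many bootstrap resamples were degenerate for the requested rule."""


class ConfigError(BqridgeError):
    """A scenario or selection configuration is inconsistent."""
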