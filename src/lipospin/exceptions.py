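"""Exception hierarchy shared by all analysis stages."""


class LipospinError(Exception):
    """Base class for all package errors."""


class ValidationError(LipospinError, ValueError):
    """Input violates a documented invariant (range, ordering, size)."""


class ParseError(LipospinError, ValueError):
    """A data file could not be parsed; message names the offending line."""


class ConfigError(LipospinError, ValueError):
    """Configuration contains an unknown key or an out-of-range value."""


class ExtractionError(LipospinError, RuntimeError):
    """Spectral feature extraction failed (missing lines, boundary extrema)."""


class FitError(LipospinError, RuntimeError):
    """A nonlinear fit failed to converge after all restarts."""


class ComputationError(LipospinError, ArithmeticError):
    """A derived quantity is undefined for the given inputs."""
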