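"""Exception hierarchy for the tnedose pipeline."""


class TnedoseError(Exception):
    """Base class for all package errors."""


class ConfigurationError(TnedoseError):
    """Invalid generator or pipeline configuration."""


class QuantificationError(TnedoseError):
    """Measurement records cannot be converted to a concentration series."""


class FittingError(TnedoseError):
    """A curve fit failed to converge or the data are degenerate."""


class DivergenceError(TnedoseError):
    """An integral over an infinite interval does not converge."""


class UndefinedRatioError(TnedoseError):
    """A dose ratio has a zero denominator."""
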