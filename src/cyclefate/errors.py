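"""Exception hierarchy shared across the package."""


class CycleFateError(Exception):
    """Base class for all package-specific errors."""


class InvalidConfigError(CycleFateError):
    """A simulation configuration violates its invariants."""


class InvalidParameterError(CycleFateError):
    """A scalar parameter is outside its admissible range."""


class InvalidProtocolError(CycleFateError):
    """A labeling protocol is ill-formed (window ordering, fixation times)."""


class SchemaError(CycleFateError):
    """A tabular input is missing required columns or violates row constraints."""


class EstimationError(CycleFateError):
    """An estimator could not produce a value from the data it was given."""


class InsufficientDataError(EstimationError):
    """Fewer data points than the estimator's minimum."""


class PeakNotBracketedError(EstimationError):
    """The pulse-chase re-entry peak lies at or beyond the last chase time."""


class FitFailureError(CycleFateError):
    """A nonlinear fit failed to converge from every starting point."""


class SingularFitError(CycleFateError):
    """A linear fit with degenerate abscissae (all x identical)."""
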