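"""Exception hierarchy for dosecurve."""


class DoseCurveError(Exception):
    """Base class for all dosecurve errors."""


class ValidationError(DoseCurveError, ValueError):
    """Invalid input data or parameters."""


class DomainError(ValidationError):
    """A model was evaluated outside its mathematical domain."""


class UnderdeterminedFitError(ValidationError):
    """Too few anchor points for the requested number of parameters."""


class ConvergenceError(DoseCurveError, RuntimeError):
    """The nonlinear fit failed to converge.

    Carries the last iterate so callers can diagnose the failure.
    """

    def __init__(self, message: str, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate
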