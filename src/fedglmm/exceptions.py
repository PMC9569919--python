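"""Exception hierarchy for fedglmm.

All errors raised by the library derive from :class:`FedGLMMError` so callers
can catch everything with one clause; subclasses distinguish bad inputs from
numerical failures of the optimisation itself.
"""


class FedGLMMError(Exception):
    """Base class for all fedglmm errors."""


class InputError(FedGLMMError, ValueError):
    """Malformed input: dimension mismatch, non-binary outcome, bad config."""


class DomainError(FedGLMMError, ValueError):
    """Parameter outside its domain (e.g. non-positive variance)."""


class ConvergenceError(FedGLMMError, RuntimeError):
    """An inner iterative solve failed to converge.

    Carries the last iterate so callers can inspect where the solve stalled.
    """

    def __init__(self, message, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate


class ProtocolError(FedGLMMError):
    """Site messages in one aggregation round are mutually inconsistent."""


class NumericalError(FedGLMMError, ArithmeticError):
    """A computed statistic is non-finite."""


class SingularityError(FedGLMMError, RuntimeError):
    """The Newton system could not be made well-posed by the adaptive ridge."""


class SweepError(FedGLMMError, RuntimeError):
    """Every fit in a penalty-grid sweep failed."""

    def __init__(self, message, failures=None):
        super().__init__(message)
        self.failures = failures or {}


class InferenceError(FedGLMMError, RuntimeError):
    """Post-fit inference is impossible (e.g. non-PSD covariance)."""


class FormatError(FedGLMMError, ValueError):
    """A data file violates the expected tabular schema."""
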