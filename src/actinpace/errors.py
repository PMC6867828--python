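"""Exceptions and warning categories shared across the package."""


class InvalidInputError(ValueError):
    """Raised when an input violates a documented precondition."""


class ConvergenceError(RuntimeError):
    """Raised when an equilibrium solver fails to satisfy mass action."""


class FitError(RuntimeError):
    """Raised when a least-squares fit fails or returns a non-physical result."""


class TrajectoryTruncatedError(RuntimeError):
    """Raised when a stochastic simulation hits its event cap.

    The partial trajectory accumulated so far is attached as ``trajectory``.
    """

    def __init__(self, message, trajectory=None):
        super().__init__(message)
        self.trajectory = trajectory


class IdentifiabilityWarning(UserWarning):
    """A fit was performed on data that poorly constrain one or more parameters."""


class DataQualityWarning(UserWarning):
    """Data violate a soft assumption (coverage, sample size, excess-titrant)."""
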