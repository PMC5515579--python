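"""Exception hierarchy shared across the package."""


class GapdynError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(GapdynError, ValueError):
    """An argument violates a documented precondition."""


class ConfigurationError(GapdynError, ValueError):
    """A configuration value is inconsistent or unknown."""


class NumericalFailureError(GapdynError, ArithmeticError):
    """The integrator produced a non-finite state.

    Carries the simulation time at which the failure was detected.
    """

    def __init__(self, message: str, time: float | None = None):
        super().__init__(message)
        self.time = time


class DomainNotFoundError(GapdynError, ValueError):
    """An expression domain or half-maximum crossing could not be located."""


class FitFailureError(GapdynError, RuntimeError):
    """A least-squares fit failed to converge; carries the last iterate."""

    def __init__(self, message: str, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate
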