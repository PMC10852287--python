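"""Exception hierarchy for the multitrophic package."""


class MultitrophicError(Exception):
    """Base class for all package-specific errors."""


class UnsupportedOrderError(MultitrophicError, ValueError):
    """Raised when a truncated-Gaussian integral order outside {0, 1, 2} is requested."""


class InfeasibleDialectError(MultitrophicError, ValueError):
    """Raised when the uniform preference dialect cannot produce nonnegative entries.

    The uniform dialect places entries on [mean - sqrt(3)*s, mean + sqrt(3)*s];
    if mean - sqrt(3)*s < 0 the support crosses zero and the strictly-positive
    convention is violated.
    """


class InfeasiblePackingError(MultitrophicError, ValueError):
    """Raised when survival fractions violate the competitive-exclusion region.

    The explicit susceptibility formulas require phi_N - r1*phi_X > 0 and
    phi_R - r2*phi_N + r1*r2*phi_X > 0; outside this region the packing
    bounds are violated and the replica-symmetric solution does not exist.
    """


class IntegrationError(MultitrophicError, RuntimeError):
    """Raised when the ODE integrator fails or produces non-finite state.

    Attributes
    ----------
    partial_state : ndarray or None
        Last finite state reached before the failure, if available.
    """

    def __init__(self, message, partial_state=None):
        super().__init__(message)
        self.partial_state = partial_state


class ConvergenceError(MultitrophicError, RuntimeError):
    """Raised when a self-consistency solver fails to reach tolerance.

    Attributes
    ----------
    best_residual : float
        Smallest residual norm achieved over all starts.
    best_start : ndarray or None
        Start point that achieved it.
    """

    def __init__(self, message, best_residual=float("inf"), best_start=None):
        super().__init__(message)
        self.best_residual = best_residual
        self.best_start = best_start


class EmptyStatisticsError(MultitrophicError, RuntimeError):
    """Raised when every system in an ensemble failed to converge."""


class UndefinedLevelError(MultitrophicError, ValueError):
    """Raised when a boundary trophic level is passed where an interior one is required."""


class UndefinedControlError(MultitrophicError, ValueError):
    """Raised when an order parameter is 0/0 (both contributions vanish)."""


class ConfigError(MultitrophicError, ValueError):
    """Raised for malformed run configurations; carries the offending keys."""

    def __init__(self, message, keys=()):
        super().__init__(message)
        self.keys = tuple(keys)
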