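"""Exception hierarchy for kinetaxis."""


class KinetaxisError(Exception):
    """Base class for all kinetaxis errors."""


class InvalidParameterError(KinetaxisError, ValueError):
    """A constructor or operation received an out-of-range parameter."""


class InvariantViolationError(KinetaxisError, RuntimeError):
    """A model invariant (positivity, normalization) was violated by the data."""


class DegenerateKernelError(KinetaxisError, RuntimeError):
    """All sensing rays at a node were annihilated; the transition kernel is undefined."""


class DegenerateNormalizationError(KinetaxisError, RuntimeError):
    """A macroscopic normalization constant vanished while its numerator did not."""


class DegenerateStateError(KinetaxisError, RuntimeError):
    """A state moment is undefined (e.g. zero total mass)."""


class ConfigurationError(KinetaxisError, ValueError):
    """A solver or experiment configuration is inconsistent (CFL, grids, keys)."""


class NotConvergedError(KinetaxisError, RuntimeError):
    """A convergence criterion was never met."""

    def __init__(self, message, closest_approach=None):
        super().__init__(message)
        self.closest_approach = closest_approach
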