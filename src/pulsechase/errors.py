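"""Exception hierarchy shared across the package."""


class PulseChaseError(Exception):
    """Base class for all package-specific errors."""


class DomainError(PulseChaseError, ValueError):
    """An input violates a mathematical precondition (sign, range, order)."""


class UndefinedFractionError(DomainError):
    """pulse + chase is zero: the fraction pulse is undefined."""


class InfiniteLifetimeError(PulseChaseError):
    """Fraction pulse >= 1: no measurable decay, lifetime is unbounded."""


class IntegrationError(PulseChaseError):
    """ODE integration failed or produced a non-finite / negative state."""


class FitError(PulseChaseError):
    """Nonlinear fit did not converge from any restart."""


class StabilityError(PulseChaseError):
    """Explicit finite-difference scheme violates its stability criterion."""


class ResolutionError(PulseChaseError):
    """Numerical grid refinement failed to converge."""


class SegmentationError(PulseChaseError):
    """Object placement or segmentation could not be completed."""
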