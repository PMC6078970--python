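"""Exception and warning types shared across the package."""


class ValidationError(ValueError):
    """Input violates a documented precondition or invariant."""


class ConservationError(ValidationError):
    """A complex distribution does not satisfy the mass-conservation laws."""


class SolverError(RuntimeError):
    """An ODE or root solver failed to converge."""


class InfeasibleEquilibriumError(RuntimeError):
    """No self-consistent free-subunit concentration exists."""


class NonGuinierCurveError(RuntimeError):
    """Low-q region of a curve is incompatible with a Guinier law."""


class FitConvergenceError(RuntimeError):
    """Nonlinear fit failed to converge or is non-identifiable."""


class SaturatedRegimeError(RuntimeError):
    """Titration slope implies a negative critical concentration."""


class InconsistentIntensityError(ValueError):
    """Measured intensity is incompatible with the stated composition."""


class SubcriticalRegimeWarning(UserWarning):
    """Total subunit concentration is at or below the critical concentration."""


class NegativeExcessWarning(UserWarning):
    """Intensity excess over the pre-complexation baseline is negative within noise."""
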