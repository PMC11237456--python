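"""Exception hierarchy for phageweapons."""


class PhageWeaponsError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(PhageWeaponsError, ValueError):
    """A parameter value or range is outside its admissible domain."""


class InvalidStateError(PhageWeaponsError, ValueError):
    """A model state violates its invariants (negative or non-finite)."""


class IntegrationError(PhageWeaponsError, RuntimeError):
    """The ODE solver failed; carries the approximate failing time."""

    def __init__(self, message: str, t_fail: float | None = None):
        super().__init__(message)
        self.t_fail = t_fail


class MetricError(PhageWeaponsError, ValueError):
    """A metric is undefined for the supplied trajectories."""


class EstimatorError(PhageWeaponsError, ValueError):
    """A life-history estimator is undefined for the supplied counts."""


class GeneratorError(PhageWeaponsError, ValueError):
    """Synthetic-data generation was requested outside the invertible domain."""


class FitError(PhageWeaponsError, ValueError):
    """A statistical model cannot be fitted to the supplied data."""
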