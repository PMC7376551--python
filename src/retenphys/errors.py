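"""Exception hierarchy shared across the package.

All domain errors derive from :class:`PhysiologyError` so callers can catch
one base class; most also derive from ``ValueError`` because they signal
invalid numeric input.
"""


class PhysiologyError(Exception):
    """Base class for all errors raised by retenphys."""


class InvalidRateError(PhysiologyError, ValueError):
    """A biomass-specific rate is zero/negative where a positive magnitude is required."""


class InvalidYieldError(PhysiologyError, ValueError):
    """A yield is zero or negative where a positive value is required."""


class UndefinedModelError(PhysiologyError, ValueError):
    """A stoichiometric model is degenerate (e.g. all charge counts zero)."""


class InvalidRecordError(PhysiologyError, ValueError):
    """A culture record violates its invariants (non-positive biomass, etc.)."""


class NoConsumptionError(InvalidRecordError):
    """Residual substrate is not below the feed concentration: nothing is consumed."""


class InvalidGasError(PhysiologyError, ValueError):
    """Off-gas fractions are inconsistent (no inert carrier in the outlet, etc.)."""


class InsufficientDataError(PhysiologyError, ValueError):
    """Fewer data points than an estimator requires."""


class SingularDesignError(PhysiologyError, ValueError):
    """Regression design matrix is singular (no spread in the regressor)."""


class OrderingError(PhysiologyError, ValueError):
    """Time series is not strictly increasing in time."""


class InvalidSampleError(PhysiologyError, ValueError):
    """A biomass sample violates its invariants."""


class SolverError(PhysiologyError, RuntimeError):
    """An iterative solver failed to converge."""


class InfeasibleStateError(PhysiologyError, ValueError):
    """A model state is physically infeasible (non-positive biomass or uptake)."""


class WashoutError(PhysiologyError, ValueError):
    """Requested dilution rate cannot sustain a steady-state culture."""


class ConfigError(PhysiologyError, ValueError):
    """Experiment configuration failed validation."""


class DependencyError(PhysiologyError, RuntimeError):
    """A pipeline stage is missing an upstream artifact."""
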