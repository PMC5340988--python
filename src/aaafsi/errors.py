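"""Exception hierarchy for the aaafsi package.

Every error raised deliberately by the package derives from :class:`AAAFSIError`
so callers can catch the package's failures with a single ``except`` clause.
"""


class AAAFSIError(Exception):
    """Base class for all aaafsi errors."""


class DomainError(AAAFSIError, ValueError):
    """An input lies outside the mathematical domain of an operation."""


class ConfigurationError(AAAFSIError, ValueError):
    """A scenario or model configuration is incomplete or inconsistent."""


class GeometryError(AAAFSIError):
    """The vessel geometry is degenerate or self-intersecting."""


class KinematicsError(AAAFSIError):
    """A deformation state is inadmissible (e.g. non-positive det F)."""


class SaturationError(AAAFSIError, OverflowError):
    """A fiber exponential term would overflow double precision.

    Carries the offending pseudo-invariant so callers can report the fiber
    stretch at which the constitutive law saturated.
    """

    def __init__(self, message: str, invariant: float | None = None):
        super().__init__(message)
        self.invariant = invariant


class ConstraintError(AAAFSIError, ValueError):
    """Missing constraint needed to determine the incompressibility pressure."""


class GridError(AAAFSIError):
    """A fluid grid is tangled or cannot be constructed."""


class StabilityError(AAAFSIError):
    """A time step violates the stability limit even after substepping."""


class SolverDivergenceError(AAAFSIError):
    """Fields became non-finite during time integration."""


class EquilibriumError(AAAFSIError):
    """The membrane ring equilibrium has no root in the admissible range."""


class InterfaceError(AAAFSIError, ValueError):
    """Fluid and solid interface discretizations do not conform."""


class CouplingError(AAAFSIError):
    """The staggered FSI subiteration failed to converge."""

    def __init__(self, message: str, residual_trace: list | None = None):
        super().__init__(message)
        self.residual_trace = residual_trace or []


class ComparisonError(AAAFSIError, ValueError):
    """Run histories cannot be compared (mismatched scenarios)."""


class LookupError_(AAAFSIError, KeyError):
    """A requested snapshot time is not stored in a history."""
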