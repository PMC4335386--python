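"""Exception hierarchy shared across the package."""


class SpinefemError(Exception):
    """Base class for all package errors."""


class ParameterError(SpinefemError, ValueError):
    """A parameter violates its documented bound."""


class GeometryError(SpinefemError):
    """A geometric construction is degenerate or inconsistent."""


class MeshError(SpinefemError):
    """Meshing failed or produced an invalid mesh."""


class ConfigurationError(SpinefemError):
    """A configuration is incomplete or contains unknown/invalid keys."""


class BoundaryConditionError(SpinefemError):
    """Boundary conditions leave the system singular."""


class SolverError(SpinefemError):
    """The linear solve failed or returned non-finite values."""


class StepSizeError(SpinefemError):
    """An incremental update inverted elements; smaller increments needed."""


class SchemaError(SpinefemError):
    """Tabular inputs have inconsistent schemas."""


class UndefinedValueError(SpinefemError):
    """A requested statistic is undefined (e.g. empty denominator)."""
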