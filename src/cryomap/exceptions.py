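"""Exception hierarchy shared across the package."""


class CryomapError(Exception):
    """Base class for all package-specific errors."""


class GeometryError(CryomapError, ValueError):
    """Invalid sensor geometry or electrode layout."""


class MeshError(CryomapError, ValueError):
    """Degenerate or inconsistent triangulation."""


class DomainError(CryomapError, ValueError):
    """Physically inadmissible input (e.g. non-positive conductivity, strain >= 1)."""


class SolverError(CryomapError, RuntimeError):
    """The finite-element system could not be solved."""


class DimensionError(CryomapError, ValueError):
    """Mismatched array shapes between mesh, pattern and measurement frames."""


class ParameterError(CryomapError, ValueError):
    """Invalid algorithm parameter (e.g. non-positive regularization weight)."""


class CalibrationError(CryomapError, ValueError):
    """Calibration fit impossible (too few points or degenerate data)."""


class NoPressError(CryomapError, ValueError):
    """No press site can be located (featureless conductance map)."""


class NoTransientError(CryomapError, ValueError):
    """No calcium transient detected in a trace."""


class RoiError(CryomapError, ValueError):
    """Region of interest empty or outside the imaged disk."""


class ProfileError(CryomapError, ValueError):
    """Radial profile cannot be sampled (ray leaves the mask immediately)."""


class InsufficientDataError(CryomapError, ValueError):
    """Too few data points for the requested statistic."""


class UndefinedCorrelationError(CryomapError, ValueError):
    """Correlation undefined (zero variance in one of the vectors)."""


class PhysicalLimitError(CryomapError, ValueError):
    """Requested phantom exceeds a physical limit (e.g. compressive strain >= 1)."""
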