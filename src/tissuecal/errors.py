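"""Exception hierarchy shared across the package."""


class TissuecalError(Exception):
    """Base class for all package-specific failures."""


class InvalidDeformationError(TissuecalError):
    """A deformation state with non-positive volume ratio (J <= 0)."""


class MeshError(TissuecalError):
    """Invalid mesh topology, geometry, or unreadable mesh file."""


class SolverError(TissuecalError):
    """Newton iteration failed to converge even after step cutting."""


class ContactError(TissuecalError):
    """Probe placement violates the initial-contact precondition."""


class CurveError(TissuecalError):
    """Malformed force-displacement curve data."""


class InsufficientSimulatedDisplacementError(TissuecalError):
    """No simulated sample reaches the experimental preload force.

    Raised by crop-and-align when rule (1) empties the simulated curve;
    the remedy is to rerun the forward model with a larger total
    displacement.
    """


class CalibrationError(TissuecalError):
    """Degenerate slopes or an invalid Brent bracket during calibration."""
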