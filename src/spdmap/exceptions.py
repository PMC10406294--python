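"""Exception hierarchy for spdmap."""


class SPDMapError(Exception):
    """Base class for all spdmap errors."""


class SymmetryError(SPDMapError):
    """A matrix expected to be symmetric is not (within tolerance)."""


class NotSPDError(SPDMapError):
    """A matrix expected to be symmetric positive definite is not."""


class DimensionError(SPDMapError):
    """Incompatible or invalid matrix dimensions."""


class DegenerateGraphError(SPDMapError):
    """A structural connectome with no off-diagonal mass or an isolated node."""


class ZeroVarianceError(SPDMapError):
    """A time series row with zero variance; correlation undefined."""


class ConvergenceError(SPDMapError):
    """An iterative scheme failed to converge within its iteration budget."""

    def __init__(self, message, gradient_norm=None, trajectory=None):
        super().__init__(message)
        self.gradient_norm = gradient_norm
        self.trajectory = trajectory


class CohortError(SPDMapError):
    """An invalid cohort: duplicate ids, mismatched sizes, missing files."""
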