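"""Exception hierarchy for pancparts."""


class PancpartsError(Exception):
    """Base class for all pancparts-specific errors."""


class DimensionalityError(PancpartsError, ValueError):
    """A volume does not have the expected number of dimensions."""


class GridError(PancpartsError, ValueError):
    """Two volumes that must share a voxel grid do not."""


class GeometryError(PancpartsError, ValueError):
    """A geometric construction is invalid (non-invertible affine, tube
    leaving the grid, ...)."""


class AnnotationError(PancpartsError, ValueError):
    """Plane-based parts annotation produced an empty or inconsistent part."""


class DegenerateShapeError(PancpartsError, ValueError):
    """A shape is too isotropic/degenerate for centerline analysis."""


class ConvergenceWarning(UserWarning):
    """Registration stopped at the iteration budget without converging."""
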