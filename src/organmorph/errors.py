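"""Exception hierarchy for the organmorph pipeline."""


class OrganMorphError(Exception):
    """Base class for all organmorph errors."""


class GeometryError(OrganMorphError):
    """Unsupported voxel-to-world geometry (non-orthogonal affine)."""


class ShapeError(OrganMorphError):
    """Array has the wrong dimensionality or an invalid shape."""


class ParameterError(OrganMorphError):
    """A parameter is outside its valid range."""


class ResolutionError(ParameterError):
    """Object too small relative to the voxel spacing to digitise."""


class LevelSetError(OrganMorphError):
    """Requested isovalue lies outside the data range (empty level set)."""


class OpenSurfaceError(OrganMorphError):
    """Mesh is not watertight, or foreground touches the volume boundary."""


class ConnectivityError(OrganMorphError):
    """Mesh connectivity is unusable (e.g. isolated vertex)."""


class EmptyInputError(OrganMorphError):
    """Operation requires a non-empty mask or point set."""


class GridMismatchError(OrganMorphError):
    """Two volumes do not share shape and spacing."""


class AlignmentError(OrganMorphError):
    """Per-vertex data length does not match the vertex count."""


class DegenerateError(OrganMorphError):
    """Degenerate geometric configuration (coincident points, zero normal)."""


class SampleSizeError(OrganMorphError):
    """Too few observations for the requested statistic."""


class UndefinedStatisticError(OrganMorphError):
    """Statistic undefined on this input (zero variance, all-zero differences)."""


class PairingError(OrganMorphError):
    """Case identifiers of two cohorts cannot be matched one-to-one."""
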