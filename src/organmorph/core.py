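"""Core containers: voxel grids and triangular surface meshes.

All physical quantities are in millimetres. A voxel with index ``(i, j, k)``
has its centre at ``origin + (i * dx, j * dy, k * dz)``; the third axis is
the slice (acquisition) axis. Meshes live in the same physical frame.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import AlignmentError, ParameterError, ShapeError


@dataclass
class VoxelVolume:
    """A 3D scalar grid with anisotropic voxel spacing.

    Carries binary masks (values {0, 1}) as well as real-valued fields
    produced by smoothing.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Scalar values, one per voxel.
    spacing : tuple of float
        Physical voxel extent ``(dx, dy, dz)`` in mm, all positive.
    origin : tuple of float
        Physical position of the centre of voxel ``(0, 0, 0)`` in mm.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ShapeError(f"expected a 3D array, got ndim={self.data.ndim}")
        if any(n < 2 for n in self.data.shape):
            raise ShapeError(f"each dimension must be >= 2, got {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ParameterError(f"spacing must be 3 positive floats, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz

    @property
    def is_isotropic(self) -> bool:
        dx, dy, dz = self.spacing
        return abs(dx - dy) < 1e-9 and abs(dx - dz) < 1e-9

    def is_mask(self) -> bool:
        """True if the grid holds only the values 0 and 1."""
        return bool(np.isin(self.data, (0, 1)).all())

    def foreground_count(self) -> int:
        return int(np.count_nonzero(self.data))

    def voxel_centres(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis physical coordinates of voxel centres (1D arrays, mm)."""
        return tuple(
            self.origin[a] + self.spacing[a] * np.arange(self.data.shape[a])
            for a in range(3)
        )


@dataclass
class TriMesh:
    """Triangular surface mesh in physical mm.

    Faces index into ``vertices``; an optional scalar (e.g. local curvature)
    may be attached per vertex.
    """

    vertices: np.ndarray
    faces: np.ndarray
    per_vertex_scalar: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ShapeError("vertices must be an (n, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ShapeError("faces must be an (m, 3) array")
        if len(self.faces) and (self.faces.min() < 0 or self.faces.max() >= len(self.vertices)):
            raise ShapeError("face indices out of range")
        degenerate = (
            (self.faces[:, 0] == self.faces[:, 1])
            | (self.faces[:, 1] == self.faces[:, 2])
            | (self.faces[:, 0] == self.faces[:, 2])
        )
        if degenerate.any():
            raise ShapeError(f"{int(degenerate.sum())} degenerate faces (repeated vertex)")
        if self.per_vertex_scalar is not None:
            self.per_vertex_scalar = np.asarray(self.per_vertex_scalar, dtype=np.float64)
            if self.per_vertex_scalar.shape != (len(self.vertices),):
                raise AlignmentError(
                    f"per-vertex scalar length {self.per_vertex_scalar.shape} "
                    f"does not match vertex count {len(self.vertices)}"
                )

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def edges(self) -> np.ndarray:
        """Undirected unique edges as an (e, 2) sorted-index array."""
        e = np.concatenate([self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]])
        e = np.sort(e, axis=1)
        return np.unique(e, axis=0)

    def edge_face_counts(self) -> np.ndarray:
        """For each unique undirected edge, the number of incident faces."""
        e = np.concatenate([self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]])
        e = np.sort(e, axis=1)
        _, counts = np.unique(e, axis=0, return_counts=True)
        return counts

    def is_watertight(self) -> bool:
        """True if every undirected edge is shared by exactly two faces."""
        counts = self.edge_face_counts()
        return bool(len(counts)) and bool((counts == 2).all())

    def euler_characteristic(self) -> int:
        return self.n_vertices - len(self.edges()) + self.n_faces

    def signed_volume(self) -> float:
        """Enclosed volume (mm^3) by the divergence theorem; sign follows winding."""
        a = self.vertices[self.faces[:, 0]]
        b = self.vertices[self.faces[:, 1]]
        c = self.vertices[self.faces[:, 2]]
        return float(np.einsum("ij,ij->", a, np.cross(b, c)) / 6.0)

    def face_normals(self, normalise: bool = True) -> np.ndarray:
        a = self.vertices[self.faces[:, 0]]
        b = self.vertices[self.faces[:, 1]]
        c = self.vertices[self.faces[:, 2]]
        n = np.cross(b - a, c - a)
        if normalise:
            lengths = np.linalg.norm(n, axis=1, keepdims=True)
            lengths[lengths == 0] = 1.0
            n = n / lengths
        return n

    def face_centroids(self) -> np.ndarray:
        return self.vertices[self.faces].mean(axis=1)

    def with_scalar(self, scalar: np.ndarray) -> "TriMesh":
        return TriMesh(self.vertices, self.faces, per_vertex_scalar=scalar)
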