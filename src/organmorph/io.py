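"""Reading and writing volumes (NIfTI-1) and meshes (ASCII PLY).

Masks are exchanged as NIfTI-1 with an orthogonal (axis-aligned, possibly
flipped or permuted) voxel-to-world transform; anything oblique is rejected
rather than resampled. On load the grid is normalised to a right-handed,
positively-spaced layout so downstream code never sees flips.
"""
from __future__ import annotations

import os

import nibabel as nib
import numpy as np
import trimesh as _trimesh

from .core import TriMesh, VoxelVolume
from .errors import AlignmentError, GeometryError, ShapeError

_ORTHO_TOL = 1e-6


def _orthogonal_decomposition(affine: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split an axis-aligned affine into a data-axis -> world-axis map and scales.

    Returns (perm, scales) where data axis ``j`` maps to world axis ``perm[j]``
    with signed step ``scales[j]``. Raises GeometryError for oblique affines.
    """
    m = np.asarray(affine, dtype=float)[:3, :3]
    perm = np.full(3, -1, dtype=int)
    scales = np.zeros(3)
    for j in range(3):
        col = m[:, j]
        nz = np.flatnonzero(np.abs(col) > _ORTHO_TOL * max(1.0, np.abs(col).max()))
        if len(nz) != 1:
            raise GeometryError("non-orthogonal (oblique) voxel-to-world transform")
        perm[j] = nz[0]
        scales[j] = col[nz[0]]
    if len(set(perm.tolist())) != 3:
        raise GeometryError("degenerate voxel-to-world transform")
    return perm, scales


def read_mask(path: str | os.PathLike) -> VoxelVolume:
    """Read a binary segmentation mask from a NIfTI-1 file.

    Values are binarised at 0.5 so probabilistic maps degrade gracefully.
    Spacing is taken from the affine; flipped/permuted axes are normalised
    to a right-handed grid with positive spacing.
    """
    img = nib.load(os.fspath(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ShapeError(f"expected a 3D image, got ndim={data.ndim}")
    perm, scales = _orthogonal_decomposition(img.affine)
    origin = np.asarray(img.affine[:3, 3], dtype=float)

    # reorder data axes so data axis j corresponds to world axis j
    inv = np.argsort(perm)
    data = np.transpose(data, axes=inv)
    scales = scales[inv]
    origin_w = np.empty(3)
    for j in range(3):
        origin_w[j] = origin[j]
    # flip negative-step axes, moving the origin to the new first voxel
    for j in range(3):
        if scales[j] < 0:
            data = np.flip(data, axis=j)
            origin_w[j] = origin_w[j] + scales[j] * (data.shape[j] - 1)
            scales[j] = -scales[j]
    mask = (np.asarray(data, dtype=np.float64) > 0.5).astype(np.uint8)
    return VoxelVolume(mask, spacing=tuple(scales), origin=tuple(origin_w))


def write_mask(vol: VoxelVolume, path: str | os.PathLike) -> None:
    """Write a mask to NIfTI-1; round-trips data, spacing and origin."""
    affine = np.eye(4)
    affine[0, 0], affine[1, 1], affine[2, 2] = vol.spacing
    affine[:3, 3] = vol.origin
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=np.uint8), affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, os.fspath(path))


def write_mesh(mesh: TriMesh, path: str | os.PathLike) -> None:
    """Write a mesh as ASCII PLY, with an optional per-vertex ``curvature`` property."""
    tm = _trimesh.Trimesh(mesh.vertices, mesh.faces, process=False)
    if mesh.per_vertex_scalar is not None:
        if len(mesh.per_vertex_scalar) != mesh.n_vertices:
            raise AlignmentError("scalar length does not match vertex count")
        tm.vertex_attributes["curvature"] = np.asarray(mesh.per_vertex_scalar, dtype=np.float64)
    payload = tm.export(file_type="ply", encoding="ascii", include_attributes=True)
    if isinstance(payload, str):
        payload = payload.encode()
    with open(path, "wb") as fh:
        fh.write(payload)


def read_mesh(path: str | os.PathLike) -> TriMesh:
    """Read a PLY mesh written by :func:`write_mesh` (recovers ``curvature``)."""
    tm = _trimesh.load(os.fspath(path), process=False, force="mesh")
    scalar = None
    if "curvature" in tm.vertex_attributes:
        scalar = np.asarray(tm.vertex_attributes["curvature"], dtype=np.float64).ravel()
    else:
        raw = tm.metadata.get("_ply_raw", {}).get("vertex", {}).get("data", {})
        if isinstance(raw, dict) and "curvature" in raw:
            scalar = np.asarray(raw["curvature"], dtype=np.float64).ravel()
        elif hasattr(raw, "dtype") and raw.dtype.names and "curvature" in raw.dtype.names:
            scalar = np.asarray(raw["curvature"], dtype=np.float64).ravel()
    return TriMesh(np.asarray(tm.vertices), np.asarray(tm.faces), per_vertex_scalar=scalar)
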