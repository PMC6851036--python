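"""Segmentation- and feature-agreement metrics.

Overlap between binary masks is scored by the Dice similarity coefficient
and the Jaccard index; contour disagreement by the modified Hausdorff
distance (Dubuisson-Jain max of mean directed nearest-neighbour distances)
between boundary-voxel centres in physical mm; and per-case feature errors
by MAE, RMSE and mean absolute percentage error (mean +/- SD across cases).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .core import VoxelVolume
from .errors import EmptyInputError, GridMismatchError, SampleSizeError
from .morphology import DEFAULT_NEIGHBOURHOOD, measure_case
from .reconstruct import ReconstructionParams


@dataclass
class EvaluationReport:
    """One predicted-vs-truth comparison (single case)."""

    dsc: float
    jaccard: float
    mhd: float                  # mm
    volume_mae: float           # cm^3
    volume_rmse: float          # cm^3
    volume_mape_mean: float     # %
    volume_mape_sd: float       # %
    curvature_mae: float        # 1/mm
    curvature_rmse: float       # 1/mm
    curvature_mape_mean: float  # %
    curvature_mape_sd: float    # %


def _check_same_grid(a: VoxelVolume, b: VoxelVolume) -> None:
    if a.shape != b.shape or any(
        abs(sa - sb) > 1e-9 for sa, sb in zip(a.spacing, b.spacing)
    ):
        raise GridMismatchError(
            f"masks must share shape and spacing; got {a.shape}/{a.spacing} "
            f"vs {b.shape}/{b.spacing}"
        )


def dice(a: VoxelVolume, b: VoxelVolume) -> float:
    """Dice similarity coefficient 2|A^B| / (|A|+|B|); both empty -> 1."""
    _check_same_grid(a, b)
    am = np.asarray(a.data) > 0
    bm = np.asarray(b.data) > 0
    denom = am.sum() + bm.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(am, bm).sum() / denom)


def jaccard(a: VoxelVolume, b: VoxelVolume) -> float:
    """Jaccard index |A^B| / |AvB|; both empty -> 1."""
    _check_same_grid(a, b)
    am = np.asarray(a.data) > 0
    bm = np.asarray(b.data) > 0
    union = np.logical_or(am, bm).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(am, bm).sum() / union)


def boundary_points(mask: VoxelVolume) -> np.ndarray:
    """Physical coordinates (mm) of boundary voxel centres.

    A foreground voxel is boundary if any of its 6 face neighbours is
    background (the mask is padded conceptually with background).
    """
    m = np.asarray(mask.data) > 0
    if not m.any():
        raise EmptyInputError("mask has no foreground voxels")
    interior = ndimage.binary_erosion(m, structure=ndimage.generate_binary_structure(3, 1))
    idx = np.argwhere(m & ~interior)
    return np.asarray(mask.origin) + idx * np.asarray(mask.spacing)


def modified_hausdorff(a_points: np.ndarray, b_points: np.ndarray) -> float:
    """Modified Hausdorff distance between two point sets (mm):
    max of the two mean directed nearest-neighbour distances."""
    a = np.atleast_2d(np.asarray(a_points, dtype=np.float64))
    b = np.atleast_2d(np.asarray(b_points, dtype=np.float64))
    if len(a) == 0 or len(b) == 0:
        raise EmptyInputError("modified Hausdorff needs two non-empty point sets")
    d_ab = cKDTree(b).query(a)[0].mean()
    d_ba = cKDTree(a).query(b)[0].mean()
    return float(max(d_ab, d_ba))


def error_stats(
    truth: np.ndarray, pred: np.ndarray
) -> tuple[float, float, float, float]:
    """MAE, RMSE and MAPE (mean, SD) between paired truth/prediction lists.

    MAPE terms with zero truth are excluded; the SD is the sample SD (n-1),
    0 for a single retained case.
    """
    t = np.asarray(truth, dtype=np.float64)
    p = np.asarray(pred, dtype=np.float64)
    if t.shape != p.shape or t.ndim != 1 or len(t) < 1:
        raise SampleSizeError("error_stats needs two equal-length lists with n >= 1")
    err = t - p
    mae = float(np.abs(err).mean())
    rmse = float(np.sqrt((err**2).mean()))
    nonzero = t != 0
    if not nonzero.any():
        return mae, rmse, float("nan"), float("nan")
    with np.errstate(over="ignore", invalid="ignore"):
        ape = 100.0 * np.abs(err[nonzero]) / np.abs(t[nonzero])
        mape_sd = float(ape.std(ddof=1)) if len(ape) > 1 else 0.0
    return mae, rmse, float(ape.mean()), mape_sd


def evaluate_pair(
    truth_mask: VoxelVolume,
    pred_mask: VoxelVolume,
    params: ReconstructionParams | None = None,
    k: int = DEFAULT_NEIGHBOURHOOD,
) -> EvaluationReport:
    """Full single-case evaluation: overlap, contour distance and the
    morphological-feature errors between the two masks."""
    _check_same_grid(truth_mask, pred_mask)
    d = dice(truth_mask, pred_mask)
    j = jaccard(truth_mask, pred_mask)
    mhd = modified_hausdorff(boundary_points(truth_mask), boundary_points(pred_mask))
    truth_rep = measure_case(truth_mask, params, k=k, case_id="truth")
    pred_rep = measure_case(pred_mask, params, k=k, case_id="pred")
    v = error_stats([truth_rep.volume_cm3], [pred_rep.volume_cm3])
    c = error_stats([truth_rep.global_curvature], [pred_rep.global_curvature])
    return EvaluationReport(
        dsc=d, jaccard=j, mhd=mhd,
        volume_mae=v[0], volume_rmse=v[1], volume_mape_mean=v[2], volume_mape_sd=v[3],
        curvature_mae=c[0], curvature_rmse=c[1], curvature_mape_mean=c[2],
        curvature_mape_sd=c[3],
    )
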