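"""Localization and segmentation evaluation metrics.

Localization: per-center Euclidean distance R, mean localization distance
(MLD) with population standard deviation (SD), and the successful
detection rate P_t at tolerance t.  Segmentation: Dice overlap (percent),
average absolute surface distance (AAD) and Hausdorff surface distance
(HSD), computed in 3D or on the 2D mid-sagittal slice of a VB.

Surfaces are iso-surfaces of the binary volumes at level 0.5 in physical
coordinates; the vertex sets are the distance primitives.  AAD is
one-directional (automatic surface to ground truth); HSD is the symmetric
Hausdorff distance between the two vertex sets.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree
from skimage import measure

from spinevb.errors import BoundsError, GridMismatchError, ParameterError

__all__ = [
    "localization_error",
    "mld_sd",
    "detection_rate",
    "dice",
    "surface_distances",
    "midsagittal_metrics",
    "mask_surface_vertices",
]


def localization_error(pred, gt) -> float:
    """Euclidean distance R = sqrt(dx^2 + dy^2 + dz^2) in mm."""
    pred = np.asarray(pred, dtype=float)
    gt = np.asarray(gt, dtype=float)
    if not (np.all(np.isfinite(pred)) and np.all(np.isfinite(gt))):
        raise ParameterError("center coordinates must be finite")
    return float(np.linalg.norm(pred - gt))


def mld_sd(errors) -> tuple[float, float]:
    """Mean localization distance and its population standard deviation.

    SD divides by the total count N_c (population form), not N_c - 1.
    """
    errors = np.asarray(list(errors), dtype=float)
    if errors.size == 0:
        raise ParameterError("empty error list")
    mld = float(errors.mean())
    sd = float(np.sqrt(((errors - mld) ** 2).mean()))
    return mld, sd


def detection_rate(errors, t: float) -> float:
    """Percentage of centers localized within t mm (boundary counts).

    ``P_t = 100 * #{R <= t} / #centers``.
    """
    errors = np.asarray(list(errors), dtype=float)
    if errors.size == 0:
        raise ParameterError("empty error list")
    if t <= 0:
        raise ParameterError("tolerance t must be positive")
    return float(100.0 * np.count_nonzero(errors <= t) / errors.size)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A.B| / (|A| + |B|) as a percentage.

    Two empty masks are defined to agree perfectly (100%).
    """
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise GridMismatchError(f"mask shapes differ: {a.shape} vs {b.shape}")
    total = int(a.sum()) + int(b.sum())
    if total == 0:
        return 100.0
    return float(200.0 * np.count_nonzero(a & b) / total)


def mask_surface_vertices(mask: np.ndarray, spacing) -> np.ndarray:
    """Iso-surface (level 0.5) vertex set of a binary volume, in mm.

    The mask is zero-padded by one voxel so surfaces of structures touching
    the array border are closed; vertex coordinates are relative to the
    unpadded voxel (0,0,0) center.
    """
    mask = np.asarray(mask).astype(float)
    if not np.any(mask):
        raise ParameterError("cannot extract a surface from an empty mask")
    spacing = np.asarray(spacing, dtype=float)
    padded = np.pad(mask, 1)
    verts, _, _, _ = measure.marching_cubes(padded, level=0.5, spacing=tuple(spacing))
    return verts - spacing[None, :]


def _contour_vertices_2d(mask2d: np.ndarray, spacing2) -> np.ndarray:
    """Iso-contour (level 0.5) vertex set of a binary 2D slice, in mm."""
    mask2d = np.asarray(mask2d).astype(float)
    if not np.any(mask2d):
        raise ParameterError("cannot extract a contour from an empty slice")
    spacing2 = np.asarray(spacing2, dtype=float)
    padded = np.pad(mask2d, 1)
    contours = measure.find_contours(padded, level=0.5)
    verts = np.concatenate(contours, axis=0) - 1.0
    return verts * spacing2[None, :]


def _vertex_set_distances(
    auto_verts: np.ndarray, gt_verts: np.ndarray, symmetric_aad: bool
) -> tuple[float, float]:
    d_auto = cKDTree(gt_verts).query(auto_verts)[0]
    d_gt = cKDTree(auto_verts).query(gt_verts)[0]
    if symmetric_aad:
        aad = float((d_auto.sum() + d_gt.sum()) / (len(d_auto) + len(d_gt)))
    else:
        aad = float(d_auto.mean())
    hsd = float(max(d_auto.max(), d_gt.max()))
    return aad, hsd


def surface_distances(
    auto: np.ndarray, gt: np.ndarray, spacing, symmetric_aad: bool = False
) -> tuple[float, float]:
    """AAD and HSD (mm) between two binary masks on the same grid.

    AAD averages, over the automatic surface's vertices, the distance to
    the nearest ground-truth vertex (one-directional by default; a
    symmetric average is available behind the flag).  HSD is the symmetric
    Hausdorff distance of the two vertex sets.
    """
    auto = np.asarray(auto).astype(bool)
    gt = np.asarray(gt).astype(bool)
    if auto.shape != gt.shape:
        raise GridMismatchError(f"mask shapes differ: {auto.shape} vs {gt.shape}")
    auto_verts = mask_surface_vertices(auto, spacing)
    gt_verts = mask_surface_vertices(gt, spacing)
    return _vertex_set_distances(auto_verts, gt_verts, symmetric_aad)


def midsagittal_metrics(
    auto: np.ndarray,
    gt: np.ndarray,
    spacing,
    center,
    sagittal_axis: int = 0,
    origin=None,
    symmetric_aad: bool = False,
) -> dict:
    """Dice/AAD/HSD on the mid-sagittal slice through a VB center.

    The slice is the one containing the (rounded) VB center along the
    left-right axis; contours are 2D iso-lines at level 0.5.
    """
    auto = np.asarray(auto).astype(bool)
    gt = np.asarray(gt).astype(bool)
    if auto.shape != gt.shape:
        raise GridMismatchError(f"mask shapes differ: {auto.shape} vs {gt.shape}")
    spacing = np.asarray(spacing, dtype=float)
    origin = np.zeros(3) if origin is None else np.asarray(origin, dtype=float)
    center = np.asarray(center, dtype=float)
    k = int(np.rint((center[sagittal_axis] - origin[sagittal_axis])
                    / spacing[sagittal_axis]))
    if not 0 <= k < auto.shape[sagittal_axis]:
        raise BoundsError(
            f"mid-sagittal slice {k} outside axis of length "
            f"{auto.shape[sagittal_axis]}"
        )
    sl = [slice(None)] * 3
    sl[sagittal_axis] = k
    auto2d = auto[tuple(sl)]
    gt2d = gt[tuple(sl)]
    spacing2 = np.delete(spacing, sagittal_axis)
    result = {"dice_pct": dice(auto2d, gt2d), "slice_index": k}
    if np.any(auto2d) and np.any(gt2d):
        aad, hsd = _vertex_set_distances(
            _contour_vertices_2d(auto2d, spacing2),
            _contour_vertices_2d(gt2d, spacing2),
            symmetric_aad,
        )
        result["aad_mm"] = aad
        result["hsd_mm"] = hsd
    else:
        result["aad_mm"] = float("nan")
        result["hsd_mm"] = float("nan")
    return result
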