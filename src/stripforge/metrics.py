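"""Evaluation statistics for brain-mask pairs and time-series mask stacks.

Pairwise metrics: Dice overlap (%), symmetric mean and maximum (Hausdorff)
surface distances (mm), percent difference in total volume, sensitivity
and specificity (%), and the percent of exposed boundary voxels (EBV) — a
boundary-roughness statistic counting brain boundary voxels with strictly
more non-brain than brain neighbors in their 26-neighborhood.

Stack metric: percent of discordant voxels (DV) across co-registered
time frames, relative to the union of brain voxels over frames.  Inputs
must be pre-aligned.

Conventions: surface voxels are mask voxels with at least one face
(6-connected) neighbor of the opposite class; everything outside the grid
counts as non-brain.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .volumes import VolumeGeometry

__all__ = [
    "MaskMetricsReport",
    "dice",
    "surface_distances",
    "volume_difference",
    "sensitivity_specificity",
    "exposed_boundary_voxels",
    "discordant_voxels",
    "evaluate_masks",
]


@dataclass
class MaskMetricsReport:
    dice_pct: float
    mean_surface_distance_mm: float
    hausdorff_mm: float
    volume_diff_pct: float          # absolute value; sign kept separately
    volume_diff_signed_pct: float
    sensitivity_pct: float | None
    specificity_pct: float | None
    ebv_pct: float

    def as_dict(self) -> dict:
        return asdict(self)


def _as_masks(a, b):
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    if a.shape != b.shape:
        raise ValueError("masks must share a grid")
    return a, b


def dice(a, b) -> float:
    """Dice overlap as a percentage: 200 |a∩b| / (|a| + |b|); 0 if both empty."""
    a, b = _as_masks(a, b)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 0.0
    return float(200.0 * np.logical_and(a, b).sum() / denom)


def _boundary(mask: np.ndarray) -> np.ndarray:
    struct = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
    eroded = ndimage.binary_erosion(mask, structure=struct, border_value=0)
    return mask & ~eroded


def surface_distances(a, b, geometry: VolumeGeometry) -> tuple[float, float]:
    """Symmetric (mean, max) surface distance between two masks, in mm.

    Distances are measured between boundary voxel centers of the two
    masks; the mean pools both directions and the max is the symmetric
    Hausdorff distance.
    """
    a, b = _as_masks(a, b)
    if not a.any() or not b.any():
        raise ValueError("surface distances require two nonempty masks")
    voxel = np.asarray(geometry.voxel_size)
    pa = np.argwhere(_boundary(a)) * voxel
    pb = np.argwhere(_boundary(b)) * voxel
    d_ab = cKDTree(pb).query(pa, k=1)[0]
    d_ba = cKDTree(pa).query(pb, k=1)[0]
    pooled = np.concatenate([d_ab, d_ba])
    return float(pooled.mean()), float(pooled.max())


def volume_difference(a, b_ref) -> tuple[float, float]:
    """Percent difference in total volume vs. a reference mask.

    Returns (absolute, signed): signed = 100 (|a| - |ref|) / |ref|.
    """
    a, b_ref = _as_masks(a, b_ref)
    ref = b_ref.sum()
    if ref == 0:
        raise ValueError("reference mask is empty")
    signed = float(100.0 * (int(a.sum()) - int(ref)) / ref)
    return abs(signed), signed


def sensitivity_specificity(a, b_ref):
    """(sensitivity %, specificity %) of mask ``a`` against a reference.

    Sensitivity = 100 TP / (TP + FN); specificity = 100 TN / (TN + FP),
    computed over the whole grid.  A value is None when the reference has
    no positive (resp. negative) voxels.
    """
    a, b_ref = _as_masks(a, b_ref)
    tp = int(np.logical_and(a, b_ref).sum())
    tn = int(np.logical_and(~a, ~b_ref).sum())
    pos = int(b_ref.sum())
    neg = b_ref.size - pos
    sens = 100.0 * tp / pos if pos else None
    spec = 100.0 * tn / neg if neg else None
    return sens, spec


_KERNEL26 = np.ones((3, 3, 3))
_KERNEL26[1, 1, 1] = 0


def exposed_boundary_voxels(a) -> float:
    """Percent of boundary voxels with more non-brain than brain neighbors.

    Boundary voxels are brain voxels with at least one non-brain neighbor
    in their 26-neighborhood; voxels beyond the grid count as non-brain.
    """
    a = np.asarray(a, bool)
    if not a.any():
        raise ValueError("EBV requires a nonempty mask")
    brain_nb = ndimage.correlate(a.astype(np.float64), _KERNEL26,
                                 mode="constant", cval=0.0)
    brain_nb = np.rint(brain_nb).astype(int)
    nonbrain_nb = 26 - brain_nb
    boundary = a & (nonbrain_nb >= 1)
    n_boundary = int(boundary.sum())
    if n_boundary == 0:
        return 0.0
    exposed = boundary & (nonbrain_nb > brain_nb)
    return float(100.0 * exposed.sum() / n_boundary)


def discordant_voxels(masks) -> float:
    """Percent of discordant voxel locations across co-registered frames.

    DV% = 100 |{voxels whose label differs across frames}| / |union of
    brain voxels over frames|.  Requires >= 2 pre-aligned masks.
    """
    masks = [np.asarray(m, bool) for m in masks]
    if len(masks) < 2:
        raise ValueError("need at least two masks")
    if any(m.shape != masks[0].shape for m in masks[1:]):
        raise ValueError("masks must share a grid")
    stack = np.stack(masks)
    union = stack.any(axis=0)
    n_union = int(union.sum())
    if n_union == 0:
        raise ValueError("union of brain voxels is empty")
    discordant = union & ~stack.all(axis=0)
    return float(100.0 * discordant.sum() / n_union)


def evaluate_masks(pred, ref, geometry: VolumeGeometry) -> MaskMetricsReport:
    """Full per-pair metrics report for a predicted vs. reference mask."""
    msd, hd = surface_distances(pred, ref, geometry)
    vd_abs, vd_signed = volume_difference(pred, ref)
    sens, spec = sensitivity_specificity(pred, ref)
    return MaskMetricsReport(
        dice_pct=dice(pred, ref),
        mean_surface_distance_mm=msd,
        hausdorff_mm=hd,
        volume_diff_pct=vd_abs,
        volume_diff_signed_pct=vd_signed,
        sensitivity_pct=sens,
        specificity_pct=spec,
        ebv_pct=exposed_boundary_voxels(pred),
    )
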