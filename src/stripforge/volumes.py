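"""Core in-memory containers for 3D volumes with voxel geometry.

All spatial quantities are denominated in millimetres.  The voxel-to-world
mapping follows the NIfTI convention: world coordinates of the voxel with
index ``i`` are ``affine @ [i, 1]``, with coordinates taken at voxel
centers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["VolumeGeometry", "GrayVolume", "LabelMap", "DistanceMap"]


@dataclass(frozen=True)
class VolumeGeometry:
    """Shape, voxel size and voxel-to-world affine of a 3D grid.

    Parameters
    ----------
    shape : tuple of int
        Grid dimensions in voxels; every entry must be >= 1.
    voxel_size : tuple of float
        Edge length of a voxel along each axis, in mm; strictly positive.
    affine : (4, 4) ndarray
        Voxel-to-world homogeneous matrix.  Its upper-left 3x3 block must
        be invertible.  Defaults to ``diag(voxel_size)`` with zero origin.
    """

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float]
    affine: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self):
        shape = tuple(int(s) for s in self.shape)
        voxel = tuple(float(v) for v in self.voxel_size)
        if len(shape) != 3 or any(s < 1 for s in shape):
            raise ValueError(f"shape must be three integers >= 1, got {shape}")
        if len(voxel) != 3 or any(v <= 0 for v in voxel):
            raise ValueError(f"voxel_size must be three positive reals, got {voxel}")
        if self.affine is None:
            aff = np.diag(list(voxel) + [1.0])
        else:
            aff = np.asarray(self.affine, dtype=float)
        if aff.shape != (4, 4):
            raise ValueError("affine must be a 4x4 matrix")
        if abs(np.linalg.det(aff[:3, :3])) < 1e-12:
            raise ValueError("affine upper-left 3x3 block is singular")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "voxel_size", voxel)
        object.__setattr__(self, "affine", aff)

    @classmethod
    def isotropic(cls, shape, voxel_mm: float = 1.0) -> "VolumeGeometry":
        if np.isscalar(shape):
            shape = (shape,) * 3
        return cls(tuple(shape), (voxel_mm,) * 3)

    def world_center(self) -> np.ndarray:
        """World coordinates of the field-of-view center."""
        c_vox = (np.asarray(self.shape, float) - 1.0) / 2.0
        return self.affine[:3, :3] @ c_vox + self.affine[:3, 3]

    def voxel_to_world(self, vox: np.ndarray) -> np.ndarray:
        vox = np.asarray(vox, float)
        return vox @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, world: np.ndarray) -> np.ndarray:
        world = np.asarray(world, float)
        inv = np.linalg.inv(self.affine)
        return world @ inv[:3, :3].T + inv[:3, 3]

    def matches(self, other: "VolumeGeometry", atol: float = 1e-5) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )


def _check_shape(data: np.ndarray, geometry: VolumeGeometry, name: str):
    if data.shape != tuple(geometry.shape):
        raise ValueError(
            f"{name} data shape {data.shape} does not match geometry {geometry.shape}"
        )


@dataclass
class GrayVolume:
    """A gray-scale 3D image with its voxel geometry."""

    data: np.ndarray
    geometry: VolumeGeometry

    def __post_init__(self):
        self.data = np.asarray(self.data)
        _check_shape(self.data, self.geometry, "GrayVolume")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("GrayVolume data must be finite")

    def copy(self) -> "GrayVolume":
        return GrayVolume(self.data.copy(), self.geometry)


@dataclass
class LabelMap:
    """Integer-labeled 3D volume split into brain and non-brain label sets.

    Label 0 is background and belongs to neither set; every nonzero label
    present in the array must be claimed by exactly one of the two sets.
    """

    labels: np.ndarray
    geometry: VolumeGeometry
    brain_label_set: frozenset = field(default_factory=frozenset)
    nonbrain_label_set: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("LabelMap requires an integer-typed array")
        _check_shape(self.labels, self.geometry, "LabelMap")
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative")
        self.brain_label_set = frozenset(int(v) for v in self.brain_label_set)
        self.nonbrain_label_set = frozenset(int(v) for v in self.nonbrain_label_set)
        if self.brain_label_set & self.nonbrain_label_set:
            raise ValueError("brain and non-brain label sets must be disjoint")
        if 0 in self.brain_label_set or 0 in self.nonbrain_label_set:
            raise ValueError("background label 0 belongs to neither set")
        present = set(int(v) for v in np.unique(self.labels)) - {0}
        unclaimed = present - self.brain_label_set - self.nonbrain_label_set
        if unclaimed:
            raise ValueError(f"labels {sorted(unclaimed)} claimed by neither set")

    @property
    def present_labels(self) -> set:
        return set(int(v) for v in np.unique(self.labels)) - {0}


@dataclass
class DistanceMap:
    """Voxel-wise signed distance to the brain boundary, in mm.

    Positive inside the brain, negative outside.
    """

    values: np.ndarray
    geometry: VolumeGeometry

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        _check_shape(self.values, self.geometry, "DistanceMap")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("DistanceMap values must be finite")
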