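"""NIfTI I/O and conforming of images to the network's canonical space.

The network operates on a canonical grid: axis-aligned, isotropic voxels
(default 1 mm), fixed shape (default 256^3), intensities min-max scaled to
[0, 1].  ``conform`` resamples any input into that space with trilinear
interpolation, recentring the field of view on the input volume; the
returned :class:`ConformRecord` carries everything needed to map continuous
predictions back to the native grid with :func:`resample_to_native`.

Conventions fixed here for reproducibility: coordinates are voxel-centered,
the world mapping is the NIfTI affine, out-of-FOV samples are zero-filled,
and the canonical grid is axis-aligned in world (RAS-like) space so that
inputs of any orientation land in a consistent axis order.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy.ndimage import map_coordinates

from .volumes import GrayVolume, LabelMap, VolumeGeometry

__all__ = [
    "read_volume",
    "write_volume",
    "write_label_map",
    "conform",
    "resample_to_native",
    "ConformRecord",
]

CANONICAL_SHAPE = (256, 256, 256)
CANONICAL_VOXEL_MM = 1.0


def _sidecar_path(path) -> Path:
    p = Path(path)
    name = p.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            name = name[: -len(suffix)]
            break
    return p.with_name(name + ".labels.json")


def read_volume(path, as_labels: bool = False):
    """Read a NIfTI-1/2 volume.

    Parameters
    ----------
    path : path-like
        A readable ``.nii`` / ``.nii.gz`` file.
    as_labels : bool
        If True, return a :class:`LabelMap`; brain / non-brain label sets
        are taken from a ``<stem>.labels.json`` sidecar if present,
        otherwise every nonzero label is treated as brain (with a warning).

    Returns
    -------
    GrayVolume or LabelMap
    """
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several error types
        raise IOError(f"cannot read NIfTI file {path!r}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data)
    if data.ndim != 3:
        raise ValueError(
            f"{path!r} is {data.ndim}-D after squeezing singleton axes; need 3-D"
        )
    voxel = tuple(float(v) for v in nib.affines.voxel_sizes(img.affine)[:3])
    geometry = VolumeGeometry(data.shape, voxel, np.asarray(img.affine, float))
    if not as_labels:
        return GrayVolume(data.astype(np.float64), geometry)
    labels = np.rint(data).astype(np.int32)
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        with open(sidecar) as fh:
            sets = json.load(fh)
        brain = frozenset(int(v) for v in sets.get("brain", []))
        nonbrain = frozenset(int(v) for v in sets.get("nonbrain", []))
    else:
        warnings.warn(
            f"no label-set sidecar for {path!r}; treating all labels as brain"
        )
        brain = frozenset(int(v) for v in np.unique(labels)) - {0}
        nonbrain = frozenset()
    return LabelMap(labels, geometry, brain, nonbrain)


def write_volume(vol, path):
    """Write a GrayVolume (float32) or raw array + geometry to NIfTI."""
    data = np.asarray(vol.data, dtype=np.float32)
    img = nib.Nifti1Image(data, vol.geometry.affine)
    nib.save(img, str(path))


def write_label_map(label_map: LabelMap, path):
    """Write a LabelMap as integer NIfTI plus a label-set JSON sidecar."""
    img = nib.Nifti1Image(
        label_map.labels.astype(np.int32), label_map.geometry.affine
    )
    nib.save(img, str(path))
    with open(_sidecar_path(path), "w") as fh:
        json.dump(
            {
                "brain": sorted(label_map.brain_label_set),
                "nonbrain": sorted(label_map.nonbrain_label_set),
            },
            fh,
        )


@dataclass(frozen=True)
class ConformRecord:
    """Resampling record sufficient to invert ``conform``."""

    native_geometry: VolumeGeometry
    conformed_geometry: VolumeGeometry
    intensity_min: float
    intensity_max: float


def _canonical_geometry(native: VolumeGeometry, voxel_mm: float, shape) -> VolumeGeometry:
    shape = tuple(int(s) for s in shape)
    affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    # Center the canonical FOV on the native FOV center (world coordinates).
    c_vox = (np.asarray(shape, float) - 1.0) / 2.0
    affine[:3, 3] = native.world_center() - affine[:3, :3] @ c_vox
    return VolumeGeometry(shape, (voxel_mm,) * 3, affine)


def _resample(data, src_geom: VolumeGeometry, dst_geom: VolumeGeometry, order=1):
    """Trilinearly sample ``data`` (on src grid) at dst voxel centers."""
    idx = np.indices(dst_geom.shape, dtype=float).reshape(3, -1).T
    world = dst_geom.voxel_to_world(idx)
    src_vox = src_geom.world_to_voxel(world).T
    out = map_coordinates(
        np.asarray(data, float), src_vox, order=order, mode="constant", cval=0.0
    )
    return out.reshape(dst_geom.shape)


def conform(
    v: GrayVolume,
    target_voxel: float = CANONICAL_VOXEL_MM,
    target_shape=CANONICAL_SHAPE,
):
    """Resample a volume to the canonical grid and scale intensities to [0, 1].

    Returns the conformed volume together with a :class:`ConformRecord`.
    A constant-intensity input degenerates min-max scaling; the output is
    all zeros and a warning is emitted.
    """
    if target_voxel <= 0:
        raise ValueError("target_voxel must be positive")
    dst_geom = _canonical_geometry(v.geometry, float(target_voxel), target_shape)
    data = _resample(v.data, v.geometry, dst_geom, order=1)
    vmin, vmax = float(data.min()), float(data.max())
    if vmax - vmin <= 0:
        warnings.warn("constant-intensity input; conformed volume set to zeros")
        scaled = np.zeros_like(data)
    else:
        scaled = (data - vmin) / (vmax - vmin)
    record = ConformRecord(v.geometry, dst_geom, vmin, vmax)
    return GrayVolume(scaled, dst_geom), record


def resample_to_native(vol: GrayVolume, record: ConformRecord) -> GrayVolume:
    """Map a continuous volume (e.g. a predicted SDT) back to native space.

    The input must live on the record's conformed grid; the output lives on
    the native grid.  Continuous maps are resampled trilinearly; callers
    threshold *after* this step so binary masks are produced in native
    space rather than resampling a binary mask.
    """
    if not vol.geometry.matches(record.conformed_geometry):
        raise ValueError("volume geometry does not match the conform record")
    data = _resample(vol.data, record.conformed_geometry, record.native_geometry)
    return GrayVolume(data, record.native_geometry)
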