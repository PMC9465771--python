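"""End-to-end skull stripping: conform -> network -> threshold -> native space.

The input image is conformed to the network's canonical grid (isotropic
voxels, fixed shape, intensities in [0, 1]), the network predicts a signed
distance transform (or class probabilities for dice-head models), the
continuous prediction is trilinearly resampled back to the native grid,
and the binary brain mask is obtained there by thresholding — the zero
level set of the SDT is the brain boundary, so the default threshold is
0 mm, exposed as a border adjustment.  No morphological post-processing
is applied by default; an optional largest-connected-component filter is
available.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage

from .io_conform import conform, resample_to_native
from .network import UNet
from .volumes import DistanceMap, GrayVolume

__all__ = ["strip", "StripResult"]


class StripResult:
    """Binary brain mask plus the skull-stripped image, both in native space."""

    def __init__(self, mask: np.ndarray, stripped: GrayVolume,
                 sdt_native: GrayVolume | None):
        self.mask = mask
        self.stripped = stripped
        self.sdt_native = sdt_native


def _largest_component(mask: np.ndarray) -> np.ndarray:
    labeled, n = ndimage.label(mask)
    if n <= 1:
        return mask
    counts = np.bincount(labeled.ravel())
    counts[0] = 0
    return labeled == counts.argmax()


def strip(image: GrayVolume, net: UNet, threshold: float | None = None,
          voxel_mm: float = 1.0, largest_cc: bool = False) -> StripResult:
    """Skull-strip a gray-scale head image of any contrast.

    Parameters
    ----------
    image : GrayVolume
        Input head image in its native geometry.
    net : UNet
        A trained network; its spec fixes the canonical input shape.
    threshold : float, optional
        Mask threshold.  For SDT heads this is a border adjustment in mm
        (default 0.0: the zero level set); for dice heads it is a brain
        probability (default 0.5).
    voxel_mm : float
        Canonical isotropic voxel size used when conforming (default 1 mm).
    largest_cc : bool
        Keep only the largest connected mask component (off by default).

    Returns
    -------
    StripResult
        Native-space binary mask and the input multiplied by it.  The
        output geometry is identical to the input geometry.
    """
    conformed, record = conform(image, target_voxel=voxel_mm,
                                target_shape=net.spec.input_shape)
    out = net.forward(conformed.data, train=False)
    if net.spec.head_mode == "sdt":
        continuous = np.asarray(out, float)
        thr = 0.0 if threshold is None else float(threshold)
    else:
        continuous = np.asarray(out[1], float)  # brain-class probability
        thr = 0.5 if threshold is None else float(threshold)

    native = resample_to_native(GrayVolume(continuous, conformed.geometry), record)
    mask = native.data > thr
    if largest_cc and mask.any():
        mask = _largest_component(mask)
    if not mask.any():
        warnings.warn("predicted brain mask is empty")
    stripped = GrayVolume(image.data * mask, image.geometry)
    sdt_native = native if net.spec.head_mode == "sdt" else None
    return StripResult(mask, stripped, sdt_native)
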