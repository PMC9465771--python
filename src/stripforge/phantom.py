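"""Synthetic whole-head label maps and intensity-based exterior labeling.

Real training data for synthesis-driven skull stripping are whole-head
tissue segmentations: several dozen brain labels (including a CSF rim)
surrounded by a handful of coarse extra-cerebral labels.  The phantom
generator emulates that structure with nested, smoothly perturbed
ellipsoidal shells — the synthesis paradigm explicitly does not require
anatomical realism, only labeled spatial and intensity variability.

The module also implements the intensity-threshold strategy used to
decorate heads with coarse extra-cerebral labels: non-zero voxels outside
the brain mask are split into ``n`` intensity bins whose thresholds
equalize the per-label voxel counts (an equal-count / quantile fit).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import zoom

from .volumes import GrayVolume, LabelMap, VolumeGeometry

__all__ = ["PhantomSpec", "generate_phantom", "merge_to_brain_mask",
           "fit_extracerebral_labels"]


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a head phantom.

    Defaults emulate an adult head on a 256^3 grid at 1 mm isotropic
    resolution: brain semi-axes of 60-85 mm, six extra-cerebral shells,
    and a few millimetres of smooth boundary perturbation.
    """

    grid_shape: tuple = (256, 256, 256)
    voxel_size_mm: float = 1.0
    n_brain_labels: int = 4
    n_nonbrain_labels: int = 6
    semi_axis_range_mm: tuple = (60.0, 85.0)
    head_margin: float = 0.35          # non-brain extent as a fraction of brain radius
    perturbation_amplitude_mm: float = 4.0
    perturbation_spacing_mm: float = 32.0
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_brain_labels < 2:
            raise ValueError("need at least 2 brain labels (interior + CSF rim)")
        if self.n_nonbrain_labels < 1:
            raise ValueError("need at least 1 non-brain label")
        lo, hi = self.semi_axis_range_mm
        if not (0 < lo <= hi):
            raise ValueError("invalid semi-axis range")
        half_extent = min(
            s * self.voxel_size_mm for s in self.grid_shape
        ) / 2.0
        outer = hi * (1.0 + self.head_margin) + self.perturbation_amplitude_mm
        if outer >= half_extent:
            raise ValueError(
                f"head (outer radius ~{outer:.1f} mm) does not nest inside the "
                f"grid (half extent {half_extent:.1f} mm)"
            )


def _smooth_field(shape, voxel_mm, spacing_mm, rng):
    """Smooth zero-mean random field via low-res normal draws + cubic upsampling."""
    low_shape = [max(2, int(np.ceil(s * voxel_mm / spacing_mm)) + 1) for s in shape]
    low = rng.standard_normal(low_shape)
    factors = [s / l for s, l in zip(shape, low_shape)]
    field = zoom(low, factors, order=3, mode="nearest", grid_mode=True)
    return field[: shape[0], : shape[1], : shape[2]]


def generate_phantom(spec: PhantomSpec) -> LabelMap:
    """Generate a head-like label map, deterministic for a fixed seed.

    Brain labels 1..n_brain occupy nested shells of a perturbed ellipsoid
    (label n_brain is the outermost, CSF-like rim); non-brain labels
    n_brain+1..n_brain+n_nonbrain form concentric extra-cerebral shells
    (skull/scalp-like); the remainder is background 0.
    """
    rng = np.random.default_rng(spec.rng_seed)
    shape = tuple(int(s) for s in spec.grid_shape)
    geometry = VolumeGeometry.isotropic(shape, spec.voxel_size_mm)

    lo, hi = spec.semi_axis_range_mm
    semi_axes = rng.uniform(lo, hi, size=3)

    idx = np.indices(shape, dtype=float)
    center = (np.asarray(shape, float) - 1.0) / 2.0
    # normalized ellipsoidal radius: 1.0 at the brain surface
    f = np.zeros(shape)
    for ax in range(3):
        f += ((idx[ax] - center[ax]) * spec.voxel_size_mm / semi_axes[ax]) ** 2
    f = np.sqrt(f)

    if spec.perturbation_amplitude_mm > 0:
        p = _smooth_field(shape, spec.voxel_size_mm, spec.perturbation_spacing_mm, rng)
        p *= spec.perturbation_amplitude_mm / max(np.abs(p).max(), 1e-12)
        f = f + p / float(np.mean(semi_axes))

    nb, nn = spec.n_brain_labels, spec.n_nonbrain_labels
    labels = np.zeros(shape, dtype=np.int32)
    # brain shells: label k covers normalized radius [(k-1)/nb, k/nb)
    for k in range(1, nb + 1):
        shell = (f >= (k - 1) / nb) & (f < k / nb)
        labels[shell] = k
    # extra-cerebral shells: thickness head_margin/nn each, outside the brain
    delta = spec.head_margin / nn
    for j in range(1, nn + 1):
        shell = (f >= 1.0 + (j - 1) * delta) & (f < 1.0 + j * delta)
        labels[shell] = nb + j

    return LabelMap(
        labels,
        geometry,
        brain_label_set=frozenset(range(1, nb + 1)),
        nonbrain_label_set=frozenset(range(nb + 1, nb + nn + 1)),
    )


def merge_to_brain_mask(s: LabelMap) -> np.ndarray:
    """Binary brain mask: true iff a voxel's label is in the brain label set."""
    if not s.brain_label_set:
        raise ValueError("label map has an empty brain label set")
    return np.isin(s.labels, sorted(s.brain_label_set))


def fit_extracerebral_labels(
    image: GrayVolume, brain: np.ndarray, n_labels: int = 6
) -> LabelMap:
    """Assign coarse extra-cerebral labels by equal-count intensity binning.

    Only non-zero voxels outside the brain mask are considered.  Thresholds
    are fit so the per-label voxel counts are as equal as possible; ties at
    a threshold are broken by deterministic voxel scan (C-order) position.
    The result labels brain voxels 1 and exterior bins 2..n_labels+1.
    """
    brain = np.asarray(brain, bool)
    if brain.shape != image.data.shape:
        raise ValueError("image and brain mask must share a grid")
    if n_labels < 1:
        raise ValueError("n_labels must be >= 1")

    labels = np.zeros(image.data.shape, dtype=np.int32)
    labels[brain] = 1

    eligible = np.flatnonzero((image.data.ravel() != 0) & ~brain.ravel())
    if eligible.size == 0:
        warnings.warn("no eligible extra-cerebral voxels; returning brain-only map")
        return LabelMap(labels, image.geometry,
                        brain_label_set=frozenset({1}) if brain.any() else frozenset(),
                        nonbrain_label_set=frozenset())

    intensities = image.data.ravel()[eligible]
    # stable equal-count split: sort by (intensity, scan order), chunk evenly
    order = np.lexsort((eligible, intensities))
    flat = labels.ravel()
    for j, chunk in enumerate(np.array_split(eligible[order], n_labels)):
        flat[chunk] = 2 + j
    return LabelMap(
        labels,
        image.geometry,
        brain_label_set=frozenset({1}) if brain.any() else frozenset(),
        nonbrain_label_set=frozenset(range(2, 2 + n_labels)),
    )
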