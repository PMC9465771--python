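"""Randomized synthesis of gray-scale training images from label maps.

Each training example is generated from an anatomical label map by

1. spatial augmentation: a random affine (translation, rotation, scale)
   composed with a diffeomorphic deformation obtained by integrating a
   smooth stationary velocity field (SVF) with scaling and squaring;
2. contrast synthesis: every label receives its own Gaussian intensity
   distribution (a reversed Bayesian mixture view of MR contrast), from
   which voxel values are drawn independently;
3. corruption: a multiplicative smooth bias field (exponential of a
   low-resolution Gaussian field), global gamma exponentiation, random
   field-of-view cropping, and partial-volume simulation by Gaussian
   blurring with sigma = r/4 followed by down/up-sampling by factor r.

All sampling ranges are uniform and deliberately exceed the realistic
range of acquisitions; the target brain mask and its signed distance
transform are derived from the *warped* labels and receive no intensity
corruption.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates, zoom

from .phantom import merge_to_brain_mask
from .sdt_loss import signed_distance
from .volumes import DistanceMap, GrayVolume, LabelMap, VolumeGeometry

__all__ = [
    "SynthesisRanges",
    "SynthesisSample",
    "SpatialTransform",
    "sample_synthesis",
    "build_transform",
    "integrate_svf",
    "apply_transform",
    "synthesize_intensities",
    "apply_bias_field",
    "sample_smooth_field",
    "apply_gamma",
    "apply_crop",
    "apply_downsample",
    "generate_training_pair",
]


@dataclass(frozen=True)
class SynthesisRanges:
    """Uniform sampling ranges for all synthesis hyperparameters.

    Defaults are the study conditions for 256 mm fields of view; the
    mm-denominated spatial ranges (translation, crop) can be rescaled for
    smaller grids with :meth:`scaled_for_fov`.
    """

    affine_translation_mm: tuple = (0.0, 50.0)
    affine_rotation_deg: tuple = (0.0, 45.0)
    affine_scale_pct: tuple = (80.0, 120.0)
    svf_spacing_mm: tuple = (8.0, 16.0)
    svf_sd_mm: tuple = (0.0, 3.0)
    label_mean: tuple = (0.0, 1.0)
    label_sd: tuple = (0.0, 0.1)
    bias_spacing_mm: tuple = (4.0, 64.0)
    bias_sd: tuple = (0.0, 0.5)
    gamma: tuple = (-0.25, 0.25)
    crop_mm: tuple = (0.0, 50.0)
    downsample_factor: tuple = (1.0, 5.0)
    crop_probability: float = 0.5
    downsample_probability: float = 0.5

    def __post_init__(self):
        for name in ("affine_translation_mm", "affine_rotation_deg",
                     "affine_scale_pct", "svf_spacing_mm", "svf_sd_mm",
                     "label_mean", "label_sd", "bias_spacing_mm", "bias_sd",
                     "gamma", "crop_mm", "downsample_factor"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name}: lower bound exceeds upper bound")
        for name in ("crop_probability", "downsample_probability"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        lo, _ = self.downsample_factor
        if lo < 1.0:
            raise ValueError("downsample factors must be >= 1")

    def scaled_for_fov(self, fov_mm: float, reference_fov_mm: float = 256.0
                       ) -> "SynthesisRanges":
        """Rescale mm-denominated FOV-relative ranges to a smaller grid.

        Translation and crop extents scale with the field of view; the
        bias-field spacing upper bound is clamped to the FOV.  Rotation,
        scaling, intensity, gamma and resolution ranges are FOV-agnostic
        and remain unchanged.
        """
        f = fov_mm / reference_fov_mm
        return SynthesisRanges(
            affine_translation_mm=tuple(v * f for v in self.affine_translation_mm),
            affine_rotation_deg=self.affine_rotation_deg,
            affine_scale_pct=self.affine_scale_pct,
            svf_spacing_mm=self.svf_spacing_mm,
            svf_sd_mm=self.svf_sd_mm,
            label_mean=self.label_mean,
            label_sd=self.label_sd,
            bias_spacing_mm=(self.bias_spacing_mm[0],
                             min(self.bias_spacing_mm[1], fov_mm)),
            bias_sd=self.bias_sd,
            gamma=self.gamma,
            crop_mm=tuple(v * f for v in self.crop_mm),
            downsample_factor=self.downsample_factor,
            crop_probability=self.crop_probability,
            downsample_probability=self.downsample_probability,
        )


@dataclass
class SynthesisSample:
    """One concrete draw of every synthesis hyperparameter."""

    translation_mm: np.ndarray        # signed, per axis
    rotation_deg: np.ndarray          # signed, per axis
    scale_pct: np.ndarray             # per axis
    svf_spacing_mm: float
    svf_sd_mm: float
    label_params: dict                # label -> (mean, sd)
    bias_spacing_mm: float
    bias_sd: float
    gamma: float
    crop_extent_mm: np.ndarray        # per axis
    crop_sides: np.ndarray            # per axis, 0 = low face, 1 = high face
    r_per_axis: np.ndarray            # >= 1; 1 on axes not selected
    apply_crop: bool
    apply_downsample: bool
    rng_seed: object = None

    def __post_init__(self):
        for lbl, (_, sd) in self.label_params.items():
            if sd < 0:
                raise ValueError(f"label {lbl}: negative intensity SD")
        if np.any(self.r_per_axis < 1):
            raise ValueError("down-sample factors must be >= 1")


def sample_synthesis(ranges: SynthesisRanges, labels, seed) -> SynthesisSample:
    """Draw one synthesis configuration; fully reproducible from the seed.

    Magnitude-range parameters with a physical sign (translation,
    rotation) receive an independent random sign per axis; all other
    scalars are drawn uniformly from their interval.  Per-label intensity
    means and SDs are drawn for labels in sorted order.  The crop and
    down-sample stages trigger via two independent Bernoulli draws; once
    down-sampling triggers, each axis is independently affected with
    probability 0.5.
    """
    labels = sorted(int(v) for v in labels)
    if not labels:
        raise ValueError("label set must be nonempty")
    rng = np.random.default_rng(seed)

    def signed(interval, n=3):
        mag = rng.uniform(*interval, size=n)
        sign = rng.choice([-1.0, 1.0], size=n)
        return mag * sign

    translation = signed(ranges.affine_translation_mm)
    rotation = signed(ranges.affine_rotation_deg)
    scale = rng.uniform(*ranges.affine_scale_pct, size=3)
    svf_spacing = float(rng.uniform(*ranges.svf_spacing_mm))
    svf_sd = float(rng.uniform(*ranges.svf_sd_mm))
    label_params = {
        lbl: (float(rng.uniform(*ranges.label_mean)),
              float(rng.uniform(*ranges.label_sd)))
        for lbl in labels
    }
    bias_spacing = float(rng.uniform(*ranges.bias_spacing_mm))
    bias_sd = float(rng.uniform(*ranges.bias_sd))
    gamma = float(rng.uniform(*ranges.gamma))
    crop_extent = rng.uniform(*ranges.crop_mm, size=3)
    crop_sides = rng.integers(0, 2, size=3)
    r = rng.uniform(*ranges.downsample_factor, size=3)
    axis_on = rng.random(size=3) < 0.5
    r = np.where(axis_on, r, 1.0)
    apply_crop = bool(rng.random() < ranges.crop_probability)
    apply_down = bool(rng.random() < ranges.downsample_probability)
    return SynthesisSample(
        translation_mm=translation, rotation_deg=rotation, scale_pct=scale,
        svf_spacing_mm=svf_spacing, svf_sd_mm=svf_sd, label_params=label_params,
        bias_spacing_mm=bias_spacing, bias_sd=bias_sd, gamma=gamma,
        crop_extent_mm=crop_extent, crop_sides=crop_sides, r_per_axis=r,
        apply_crop=apply_crop, apply_downsample=apply_down, rng_seed=seed,
    )


@dataclass
class SpatialTransform:
    """Affine matrix + SVF + composed dense displacement (mm, target grid)."""

    affine: np.ndarray                       # 4x4 world -> world forward motion
    velocity: np.ndarray | None              # (3, *low_shape) mm
    velocity_spacing_mm: float | None
    displacement: np.ndarray                 # (3, *target_shape) mm

    def __post_init__(self):
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine must be invertible")
        if not np.all(np.isfinite(self.displacement)):
            raise ValueError("displacement must be finite")


def _rotation_matrix(rotation_deg: np.ndarray) -> np.ndarray:
    """Per-axis rotations composed in fixed x-y-z order."""
    rx, ry, rz = np.deg2rad(rotation_deg)
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


def make_affine(sample: SynthesisSample, geometry: VolumeGeometry) -> np.ndarray:
    """4x4 forward affine: rotation and scaling about the volume center."""
    R = _rotation_matrix(sample.rotation_deg)
    S = np.diag(sample.scale_pct / 100.0)
    M = R @ S
    c = geometry.world_center()
    A = np.eye(4)
    A[:3, :3] = M
    A[:3, 3] = c - M @ c + sample.translation_mm
    return A


def sample_velocity(sample: SynthesisSample, geometry: VolumeGeometry, seed
                    ) -> tuple[np.ndarray, float]:
    """Draw a low-resolution SVF (mm) covering the target field of view."""
    rng = np.random.default_rng(seed)
    h = sample.svf_spacing_mm
    extent = [s * v for s, v in zip(geometry.shape, geometry.voxel_size)]
    low_shape = [max(2, int(np.ceil(e / h)) + 1) for e in extent]
    velocity = rng.normal(0.0, sample.svf_sd_mm, size=(3, *low_shape))
    return velocity, h


def integrate_svf(velocity: np.ndarray, spacing_mm: float, steps: int = 5,
                  target_geometry: VolumeGeometry | None = None) -> np.ndarray:
    """Integrate a stationary velocity field by scaling and squaring.

    The field (mm) is divided by 2**steps and self-composed ``steps``
    times on its own grid, which encourages a diffeomorphic displacement;
    the result is trilinearly resampled to the target grid if one is
    given, else returned on the velocity grid.  Edge samples clamp to the
    border value.
    """
    if steps < 0:
        raise ValueError("steps must be >= 0")
    velocity = np.asarray(velocity, float)
    low_shape = velocity.shape[1:]
    # work in voxel units of the velocity grid
    phi = velocity / spacing_mm / (2.0 ** steps)
    ident = np.indices(low_shape, dtype=float)
    for _ in range(steps):
        coords = ident + phi
        phi = phi + np.stack([
            map_coordinates(phi[c], coords, order=1, mode="nearest")
            for c in range(3)
        ])
    disp_mm = phi * spacing_mm
    if target_geometry is None:
        return disp_mm
    # velocity-grid voxel i sits at target-FOV offset i * spacing_mm
    idx = np.indices(target_geometry.shape, dtype=float)
    coords = [idx[c] * target_geometry.voxel_size[c] / spacing_mm for c in range(3)]
    return np.stack([
        map_coordinates(disp_mm[c], coords, order=1, mode="nearest")
        for c in range(3)
    ])


def build_transform(sample: SynthesisSample, geometry: VolumeGeometry,
                    svf_seed) -> SpatialTransform:
    """Compose the sampled affine with an integrated SVF deformation."""
    affine = make_affine(sample, geometry)
    if sample.svf_sd_mm > 0:
        velocity, h = sample_velocity(sample, geometry, svf_seed)
        disp = integrate_svf(velocity, h, steps=5, target_geometry=geometry)
    else:
        velocity, h = None, None
        disp = np.zeros((3, *geometry.shape))
    return SpatialTransform(affine, velocity, h, disp)


def apply_transform(s: LabelMap, t: SpatialTransform) -> LabelMap:
    """Warp a label map with nearest-neighbor sampling.

    For every target voxel at world position p, the source is sampled at
    inv(A) @ p + d(p); source positions outside the FOV map to background.
    """
    if t.displacement.shape[1:] != tuple(s.geometry.shape):
        raise ValueError("displacement is not defined on the label-map grid")
    geom = s.geometry
    idx = np.indices(geom.shape, dtype=float).reshape(3, -1).T
    world = geom.voxel_to_world(idx)
    A_inv = np.linalg.inv(t.affine)
    src_world = world @ A_inv[:3, :3].T + A_inv[:3, 3]
    src_world = src_world + t.displacement.reshape(3, -1).T
    src_vox = geom.world_to_voxel(src_world).T
    warped = map_coordinates(s.labels, src_vox, order=0, mode="constant", cval=0)
    return LabelMap(warped.reshape(geom.shape).astype(s.labels.dtype), geom,
                    s.brain_label_set, s.nonbrain_label_set)


def synthesize_intensities(s_t: LabelMap, sample: SynthesisSample,
                           seed=None) -> GrayVolume:
    """Replace each label voxel with a draw from its Gaussian distribution.

    Background stays exactly 0; negative draws clamp to 0 so subsequent
    gamma exponentiation stays well defined.
    """
    missing = s_t.present_labels - set(sample.label_params)
    if missing:
        raise ValueError(f"no intensity parameters for labels {sorted(missing)}")
    rng = np.random.default_rng(sample.rng_seed if seed is None else seed)
    out = np.zeros(s_t.geometry.shape, dtype=float)
    for lbl in sorted(s_t.present_labels):
        mean, sd = sample.label_params[lbl]
        where = s_t.labels == lbl
        draws = rng.normal(mean, sd, size=int(where.sum())) if sd > 0 else \
            np.full(int(where.sum()), mean)
        out[where] = np.maximum(draws, 0.0)
    return GrayVolume(out, s_t.geometry)


def sample_smooth_field(geometry: VolumeGeometry, spacing_mm: float,
                        sd: float, seed) -> np.ndarray:
    """Zero-mean Gaussian field drawn at low resolution, trilinearly upsampled."""
    rng = np.random.default_rng(seed)
    extent = [s * v for s, v in zip(geometry.shape, geometry.voxel_size)]
    low_shape = [max(2, int(np.ceil(e / spacing_mm)) + 1) for e in extent]
    low = rng.normal(0.0, sd, size=low_shape)
    idx = np.indices(geometry.shape, dtype=float)
    coords = [idx[c] * geometry.voxel_size[c] / spacing_mm for c in range(3)]
    return map_coordinates(low, coords, order=1, mode="nearest")


def apply_bias_field(x: GrayVolume, bias_spacing_mm: float, bias_sd: float,
                     seed) -> GrayVolume:
    """Multiply by the voxel-wise exponential of a smooth random field."""
    if bias_sd < 0:
        raise ValueError("bias_sd must be >= 0")
    if bias_sd == 0:
        return x.copy()
    field = sample_smooth_field(x.geometry, bias_spacing_mm, bias_sd, seed)
    return GrayVolume(x.data * np.exp(field), x.geometry)


def apply_gamma(x: GrayVolume, gamma: float) -> GrayVolume:
    """Global power-law contrast change: v -> v ** exp(gamma).

    Requires nonnegative input (normalize to [0, 1] first).
    """
    if x.data.min() < 0:
        raise ValueError("gamma exponentiation requires nonnegative intensities")
    return GrayVolume(np.power(x.data, np.exp(gamma)), x.geometry)


def apply_crop(x: GrayVolume, crop_extent_mm, sides) -> GrayVolume:
    """Zero out a margin on one face of each axis; grid shape is unchanged."""
    data = x.data.copy()
    for ax in range(3):
        n = int(round(float(crop_extent_mm[ax]) / x.geometry.voxel_size[ax]))
        if n >= x.geometry.shape[ax]:
            raise ValueError(f"crop consumes the entire axis {ax}")
        if n == 0:
            continue
        sl = [slice(None)] * 3
        sl[ax] = slice(0, n) if sides[ax] == 0 else slice(-n, None)
        data[tuple(sl)] = 0.0
    return GrayVolume(data, x.geometry)


def apply_downsample(x: GrayVolume, r_per_axis) -> GrayVolume:
    """Simulate acquisition at lower resolution along selected axes.

    Per-axis Gaussian blur with sigma = r/4 (in voxels) models the
    partial-volume effect, then the image is resampled down by factor r
    and trilinearly back up to the original grid.
    """
    r = np.asarray(r_per_axis, float)
    if np.any(r < 1):
        raise ValueError("down-sample factors must be >= 1")
    sigma = r / 4.0
    blurred = gaussian_filter(x.data, sigma=sigma, mode="nearest")
    if np.allclose(r, 1.0):
        return GrayVolume(blurred, x.geometry)
    low_shape = [max(1, int(round(s / f))) for s, f in zip(x.geometry.shape, r)]
    down = zoom(blurred, [l / s for l, s in zip(low_shape, x.geometry.shape)],
                order=1, mode="nearest", grid_mode=True)
    up = zoom(down, [s / l for s, l in zip(x.geometry.shape, low_shape)],
              order=1, mode="nearest", grid_mode=True)
    return GrayVolume(up[: x.geometry.shape[0], : x.geometry.shape[1],
                         : x.geometry.shape[2]], x.geometry)


def _minmax(data: np.ndarray) -> np.ndarray:
    lo, hi = float(data.min()), float(data.max())
    if hi - lo <= 0:
        return np.zeros_like(data)
    return (data - lo) / (hi - lo)


def generate_training_pair(s: LabelMap, ranges: SynthesisRanges, seed,
                           return_details: bool = False):
    """Synthesize one training example (image, target mask, target SDT).

    Pipeline: sample hyperparameters -> build affine + SVF -> warp the
    labels -> merge brain labels into the target mask and compute its SDT
    -> synthesize intensities -> bias field -> min-max normalize -> gamma
    -> crop (p = 0.5) -> blur + down-sample (p = 0.5) -> final min-max
    normalization.  The mask and SDT share the warp but receive no
    intensity corruption.  Bitwise reproducible for a fixed seed.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    seed_sample, seed_svf, seed_intensity, seed_bias = ss.spawn(4)
    labels = s.brain_label_set | s.nonbrain_label_set
    sample = sample_synthesis(ranges, labels, seed_sample)

    t = build_transform(sample, s.geometry, seed_svf)
    s_t = apply_transform(s, t)
    y_hat = merge_to_brain_mask(s_t)
    d_hat = signed_distance(y_hat, s.geometry)

    x = synthesize_intensities(s_t, sample, seed=seed_intensity)
    x = apply_bias_field(x, sample.bias_spacing_mm, sample.bias_sd, seed_bias)
    x = GrayVolume(_minmax(x.data), x.geometry)
    x = apply_gamma(x, sample.gamma)
    if sample.apply_crop:
        x = apply_crop(x, sample.crop_extent_mm, sample.crop_sides)
    if sample.apply_downsample:
        x = apply_downsample(x, sample.r_per_axis)
    x = GrayVolume(_minmax(x.data), x.geometry)
    if return_details:
        details = {"sample": sample, "transform": t, "warped_labels": s_t}
        return x, y_hat, d_hat, details
    return x, y_hat, d_hat
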