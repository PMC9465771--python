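# Methods

## Model

`stripforge` trains a convolutional network to extract the brain from a
gray-scale head volume without ever observing real images.  The training
distribution is defined generatively from whole-head anatomical label
maps: a map *s* with disjoint brain and non-brain label sets is warped by
a random spatial transform, rendered into a gray-scale image with a
random per-label Gaussian intensity mixture, and corrupted with
acquisition-like artifacts.  The supervision signal — the brain mask and
its signed distance transform — is derived from the *warped* labels and
is therefore exact by construction.

The underlying contrast assumption is the Bayesian mixture view of MR:
voxel intensity within one tissue class is unimodal Gaussian.  Run in
reverse, any assignment of (μ, σ) to labels is a valid "contrast", so a
network trained across all of them cannot key on absolute intensities and
must learn shape and relative-contrast cues instead.

## Synthesis engine (`synth`)

All hyperparameters are drawn uniformly per training step from fixed
ranges (defaults, for a 256 mm field of view):

| parameter | range | unit |
|---|---|---|
| affine translation | 0–50 (random sign per axis) | mm |
| affine rotation | 0–45 (random sign per axis) | deg |
| affine scaling | 80–120 | % |
| SVF grid spacing | 8–16 (isotropic) | mm |
| SVF standard deviation | 0–3 | mm |
| label intensity mean | 0–1 | – |
| label intensity SD | 0–0.1 | – |
| bias-field grid spacing | 4–64 | mm |
| bias-field SD | 0–0.5 | – |
| gamma exponent γ | −0.25–0.25 | – |
| FOV crop (per axis, one face) | 0–50 | mm |
| down-sample factor r (per axis) | 1–5 | – |

Cropping and down-sampling each trigger with probability 0.5
(independent draws); once down-sampling triggers, each axis participates
independently with probability 0.5.  Translation and rotation magnitudes
receive an independent random sign per axis, since one-sided draws would
bias the augmentation distribution.

The nonlinear deformation is a stationary velocity field drawn i.i.d.
normal on a coarse isotropic grid, integrated with five scaling-and-
squaring steps (halve the field five times, self-compose five times) on
its own grid, then trilinearly resampled to the image grid.  Over the
sampled envelope this produces overwhelmingly diffeomorphic warps
(positive Jacobian determinant; verified empirically in the tests).
Labels are warped with nearest-neighbor sampling; out-of-FOV sources
become background.

Stage order after intensity synthesis: bias field → min-max
normalization → gamma → crop (p = 0.5) → blur/down-sample (p = 0.5) →
final min-max normalization.  Normalization precedes gamma because the
power law v ↦ v^{exp(γ)} requires a nonnegative domain, and the final
normalization matches the test-time input contract.  Negative Gaussian
intensity draws clamp to 0 for the same reason.  Partial-volume effects
use a Gaussian blur with σ = r/4 voxels before resampling down by r and
trilinearly back up to the fixed grid.

## Loss (`sdt_loss`)

The exact Euclidean SDT is computed per voxel as the mm distance between
voxel centers of opposite classes (boundary-adjacent voxels therefore
have |d| = one voxel — the standard exact-EDT convention; the formulation
itself is convention-agnostic, so the choice is pinned here).  Voxel
anisotropy enters the metric explicitly.  The target is banded: values
clamp to ±t and voxels whose unclamped |d̂| exceeds t get weight b in the
weighted MSE; t = 5 mm and b = 0.1 by default.  Banding *and*
down-weighting are both applied, which keeps far-field gradients bounded
and small while concentrating learning near the boundary.  The network's
prediction is compared raw (linear output head, no clamping).

The alternative soft-Dice formulation sums the per-class ratio
|y⊙ŷ|/|y⊕ŷ| over the brain and non-brain softmax channels; the ratio is
1/2 per class at perfect overlap, so the similarity peaks at 1.0 and the
minimized loss is its negative.

## Network and training (`network`, `train`)

The architecture is a standard 3D U-Net: seven resolution levels by
default, two 3×3×3 convolutions with leaky-ReLU (α = 0.2) per level,
max-pooling ×2 down, nearest-neighbor ×2 up, concatenation skips, and a
task head (1-channel linear for SDT, 2-channel softmax for Dice).
Per-level filter counts default to 16·2^level capped at 256 and are fully
configurable; the decoder mirrors the encoder.  Everything — forward,
backward, Adam — is implemented on NumPy arrays (convolutions as 27
shifted-view matrix products), which keeps the dependency footprint
minimal and is fast enough for the experiment scale targeted here.

Training follows the published recipe: batch size 1, Adam at 1e-4, and a
plateau schedule that halves the learning rate whenever 20,000
optimization steps pass without a new validation-loss minimum (the
counter restarts after each halving).  Validation uses synthetic pairs
with frozen seeds, which preserves the scheduler's contract without
requiring held-out real scans.  Label maps are drawn uniformly per step.
Total step count is a required configuration value.  All randomness fans
out deterministically from one seed; fixed seeds reproduce loss
trajectories bitwise.

## Inference (`io_conform`, `strip`)

Inputs are conformed to a canonical axis-aligned grid (1 mm isotropic,
256³ by default — the grid is configurable and follows the checkpoint's
input shape) by trilinear resampling centered on the input FOV, with
min-max intensity scaling to [0, 1]; constant images degenerate to zeros
with a warning.  Coordinates are voxel-centered and the world mapping is
the NIfTI affine; out-of-FOV voxels are zero-filled.  The predicted SDT
is resampled trilinearly back to the native grid and thresholded *there*
(default 0 mm, exposed as a border adjustment), which avoids the
staircase artifacts of resampling a binary mask.  No morphological
post-processing is applied by default; a largest-connected-component
filter is optional.

## Phantoms (`phantom`)

Real training data would be multi-label whole-head segmentations.  The
phantom generator emulates their structure — not their anatomy — with
nested shells of a smoothly perturbed ellipsoid: n brain labels (the
outermost a CSF-like rim) and, outside them, n concentric extra-cerebral
shells, all on a configurable grid (256³ at 1 mm by default, with
adult-head-like 60–85 mm semi-axes).  The perturbation is a smooth
low-resolution random field added to the normalized radius, which
preserves nesting and connectivity.  The synthesis paradigm explicitly
does not require realistic anatomy, and the phantoms deliberately have
none: passing tests demonstrate that the *pipeline* learns and
generalizes across contrast, not that the model is clinically validated —
real cortical folding, thin dura, eyes and neck structures are absent,
and results on real scans are out of scope here.

The extra-cerebral labeling of real images ("maximize similarity in
voxel count per label") is implemented as equal-count quantile binning of
nonzero non-brain voxels, with ties broken by deterministic C-order voxel
scan; per-label counts then differ by at most one plus ties.

## Metrics (`metrics`)

Dice (%), symmetric mean/max (Hausdorff) surface distance over pooled
boundary-voxel sets, percent volume difference (absolute in summaries,
signed retained), sensitivity/specificity, EBV, and DV%.  Boundary
voxels for surface distances use 6-connectivity; the EBV neighbor tally
uses the 26-neighborhood, with off-grid neighbors counted as non-brain;
both choices are documented here because the statistics themselves do
not fix them.  DV% assumes pre-aligned frames; rigid alignment is out of
scope.

## The small-scale reference experiment (`toy`)

CPU-scale end-to-end runs use 32³ phantoms (8–11 mm brain semi-axes,
four extra-cerebral shells), a three-level U-Net (16/32/64 filters), and
400 optimization steps.  The FOV-relative mm ranges (translation, crop)
scale by 32/256; resolution-, intensity- and angle-denominated ranges are
unchanged, and the bias-spacing upper bound clamps to the FOV.  The SDT
model trains at 1e-3; the soft-Dice model at 3e-4, since at this problem
size larger rates collapse the class-imbalanced Dice objective onto the
all-non-brain solution.  Held-out evaluation keeps contrast, bias, gamma
and resolution randomization but disables cropping, which would delete
image evidence over voxels the ground-truth mask still counts.  These
sizes are the package's pinned reference configuration; larger grids and
longer schedules only improve results.

## Numerical choices and limitations

- Interpolation: trilinear for continuous maps and field upsampling,
  nearest-neighbor for labels; edge handling clamps to border values for
  random fields and zero-fills for images/labels.
- Rotations compose in fixed x-y-z order about the volume center; the
  crop face per axis is chosen uniformly.
- Equal-count binning, quantile ties, and pooling argmax ties resolve by
  first occurrence in C scan order for reproducibility.
- The all-true/all-false mask has no boundary: SDT and surface-distance
  functions raise on degenerate inputs rather than guessing.
- Single-channel gray-scale input only; DICOM, 4D containers and MGH
  formats are not handled.
- The NumPy network is CPU-bound and intended for method study and small
  experiments, not for training full 256³ models.
- At the toy scale, the loss-comparison experiment does not reproduce the
  boundary-roughness contrast between the two losses: the reproduction
  script measures EBV for the SDT-trained model, the Dice-trained model
  and the ground-truth masks on the same held-out renderings, and both
  models come out substantially *smoother than the truth*.  Ragged Dice
  boundaries are a property of converged, saturated voxel-wise
  predictions; a small underfit model trained for a few hundred steps
  produces smooth probability maps instead, so the smoothing advantage of
  the SDT loss has no room to manifest here.  The corresponding test
  documents this as an open gap between the small-scale experiment and
  the behaviour expected of full-scale models.
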