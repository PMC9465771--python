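"""Generate a synthetic whole-head label map and decorate a rendered image
with coarse extra-cerebral labels.

The phantom is a nested stack of smoothly perturbed ellipsoids: brain
labels (the outermost acting as a CSF-like rim) surrounded by concentric
extra-cerebral shells.  The equal-count intensity labeling splits the
non-brain, non-zero voxels of an image into bins of near-identical size.
"""

import numpy as np

from stripforge import (GrayVolume, PhantomSpec, fit_extracerebral_labels,
                        generate_phantom, merge_to_brain_mask)

spec = PhantomSpec(grid_shape=(64, 64, 64), voxel_size_mm=1.0,
                   n_brain_labels=3, n_nonbrain_labels=4,
                   semi_axis_range_mm=(16.0, 20.0),
                   perturbation_amplitude_mm=2.0, rng_seed=1)
lm = generate_phantom(spec)

print("label inventory (label: voxels):")
for label in sorted(lm.present_labels):
    kind = "brain" if label in lm.brain_label_set else "non-brain"
    print(f"  {label} ({kind}): {int((lm.labels == label).sum())}")

mask = merge_to_brain_mask(lm)
print(f"merged brain mask: {int(mask.sum())} voxels "
      f"({100 * mask.sum() / mask.size:.1f}% of the grid)")

# fake a gray-scale head image and re-derive extra-cerebral labels from it
rng = np.random.default_rng(0)
intensity = np.where(lm.labels > 0, rng.random(lm.geometry.shape), 0.0)
relabeled = fit_extracerebral_labels(GrayVolume(intensity, lm.geometry),
                                     mask, n_labels=4)
counts = [int((relabeled.labels == l).sum()) for l in range(2, 6)]
print(f"equal-count exterior bins: {counts} "
      f"(max pairwise difference {max(counts) - min(counts)})")
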