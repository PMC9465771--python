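import numpy as np
import pytest
from scipy.spatial.distance import cdist

from stripforge import (VolumeGeometry, dice, discordant_voxels,
                        evaluate_masks, exposed_boundary_voxels,
                        sensitivity_specificity, surface_distances,
                        volume_difference)

GEOM = VolumeGeometry.isotropic(12)


def boundary_oracle(mask):
    """6-connected boundary voxels (outside the grid counts as non-brain)."""
    out = np.zeros_like(mask)
    for idx in np.argwhere(mask):
        for ax in range(3):
            for d in (-1, 1):
                j = idx.copy()
                j[ax] += d
                if j[ax] < 0 or j[ax] >= mask.shape[ax]:
                    out[tuple(idx)] = True
                    break
                if not mask[tuple(j)]:
                    out[tuple(idx)] = True
                    break
            if out[tuple(idx)]:
                break
    return out


def surface_oracle(a, b, voxel):
    pa = np.argwhere(boundary_oracle(a)) * np.asarray(voxel)
    pb = np.argwhere(boundary_oracle(b)) * np.asarray(voxel)
    d_ab = cdist(pa, pb).min(axis=1)
    d_ba = cdist(pb, pa).min(axis=1)
    pooled = np.concatenate([d_ab, d_ba])
    return pooled.mean(), pooled.max()


def ebv_oracle(mask):
    exposed = total = 0
    for idx in np.argwhere(mask):
        brain = nonbrain = 0
        for dz in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    if dz == dy == dx == 0:
                        continue
                    j = idx + (dz, dy, dx)
                    if np.any(j < 0) or np.any(j >= mask.shape):
                        nonbrain += 1
                    elif mask[tuple(j)]:
                        brain += 1
                    else:
                        nonbrain += 1
        if nonbrain >= 1:
            total += 1
            if nonbrain > brain:
                exposed += 1
    return 100.0 * exposed / total if total else 0.0


class TestDice:
    def test_identical_masks(self, rng):
        m = rng.random((12, 12, 12)) < 0.3
        m[0, 0, 0] = True
        assert dice(m, m) == 100.0

    def test_disjoint_and_empty(self):
        a = np.zeros((4, 4, 4), bool)
        b = np.zeros((4, 4, 4), bool)
        a[0], b[2] = True, True
        assert dice(a, b) == 0.0
        assert dice(np.zeros((4, 4, 4), bool), np.zeros((4, 4, 4), bool)) == 0.0

    def test_half_overlap_arithmetic(self):
        a = np.zeros((10, 10, 10), bool)
        b = np.zeros((10, 10, 10), bool)
        a.ravel()[:100] = True
        b.ravel()[50:150] = True
        assert dice(a, b) == 50.0

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dice(np.zeros((2, 2, 2), bool), np.zeros((3, 3, 3), bool))


class TestSurfaceDistances:
    def test_identical_masks_zero(self):
        m = np.zeros((12, 12, 12), bool)
        m[3:8, 3:8, 3:8] = True
        assert surface_distances(m, m, GEOM) == (0.0, 0.0)

    def test_concentric_cubes_against_oracle(self):
        a = np.zeros((12, 12, 12), bool)
        b = np.zeros((12, 12, 12), bool)
        a[4:8, 4:8, 4:8] = True
        b[2:10, 2:10, 2:10] = True
        mean, mx = surface_distances(a, b, GEOM)
        omean, omx = surface_oracle(a, b, GEOM.voxel_size)
        assert np.isclose(mean, omean, atol=1e-9)
        assert np.isclose(mx, omx, atol=1e-9)

    def test_random_masks_match_oracle(self, rng):
        geom = VolumeGeometry((8, 8, 8), (1.0, 1.3, 2.0),
                              np.diag([1.0, 1.3, 2.0, 1.0]))
        for _ in range(5):
            a = rng.random((8, 8, 8)) < 0.4
            b = rng.random((8, 8, 8)) < 0.4
            if not (a.any() and b.any()):
                continue
            mean, mx = surface_distances(a, b, geom)
            omean, omx = surface_oracle(a, b, geom.voxel_size)
            assert np.isclose(mean, omean, atol=1e-9)
            assert np.isclose(mx, omx, atol=1e-9)

    def test_empty_mask_rejected(self):
        m = np.zeros((4, 4, 4), bool)
        m[1] = True
        with pytest.raises(ValueError):
            surface_distances(m, np.zeros((4, 4, 4), bool), GEOM)


class TestVolumeDifference:
    def test_equal_volumes(self, rng):
        m = rng.random((6, 6, 6)) < 0.5
        m[0, 0, 0] = True
        assert volume_difference(m, m) == (0.0, 0.0)

    def test_ten_percent(self):
        a = np.zeros((10, 10, 10), bool)
        b = np.zeros((10, 10, 10), bool)
        a.ravel()[:110] = True
        b.ravel()[:100] = True
        assert volume_difference(a, b) == (10.0, 10.0)
        assert np.isclose(volume_difference(b, a)[1], -100 * 10 / 110)

    def test_empty_reference_rejected(self):
        a = np.ones((3, 3, 3), bool)
        with pytest.raises(ValueError):
            volume_difference(a, np.zeros((3, 3, 3), bool))


class TestSensitivitySpecificity:
    def test_perfect(self, rng):
        m = rng.random((6, 6, 6)) < 0.5
        m[0, 0, 0], m[-1, -1, -1] = True, False
        assert sensitivity_specificity(m, m) == (100.0, 100.0)

    def test_full_prediction(self, rng):
        ref = rng.random((6, 6, 6)) < 0.5
        ref[0, 0, 0], ref[-1, -1, -1] = True, False
        sens, spec = sensitivity_specificity(np.ones((6, 6, 6), bool), ref)
        assert sens == 100.0 and spec == 0.0

    def test_hand_tallied_counts(self):
        a = np.zeros((2, 2, 2), bool)
        ref = np.zeros((2, 2, 2), bool)
        ref.ravel()[:4] = True          # 4 positives
        a.ravel()[:3] = True            # TP=3, FN=1
        a.ravel()[6] = True             # FP=1, TN=3
        sens, spec = sensitivity_specificity(a, ref)
        assert np.isclose(sens, 75.0) and np.isclose(spec, 75.0)

    def test_degenerate_reference_reports_missing(self):
        empty = np.zeros((3, 3, 3), bool)
        full = np.ones((3, 3, 3), bool)
        assert sensitivity_specificity(empty, empty)[0] is None
        assert sensitivity_specificity(full, full)[1] is None


class TestExposedBoundaryVoxels:
    def test_solid_cube_matches_oracle(self):
        m = np.zeros((12, 12, 12), bool)
        m[3:9, 3:9, 3:9] = True
        assert np.isclose(exposed_boundary_voxels(m), ebv_oracle(m), atol=1e-9)

    def test_isolated_voxel_fully_exposed(self):
        m = np.zeros((5, 5, 5), bool)
        m[2, 2, 2] = True
        assert exposed_boundary_voxels(m) == 100.0

    def test_spike_on_cube_counts_as_exposed(self):
        cube = np.zeros((12, 12, 12), bool)
        cube[3:9, 3:9, 3:9] = True
        spiked = cube.copy()
        spiked[6, 6, 9:11] = True  # 1-voxel-thick spike
        assert np.isclose(exposed_boundary_voxels(spiked), ebv_oracle(spiked),
                          atol=1e-9)
        assert exposed_boundary_voxels(spiked) > exposed_boundary_voxels(cube)

    def test_random_masks_match_oracle(self, rng):
        for _ in range(3):
            m = rng.random((7, 7, 7)) < 0.45
            if not m.any():
                continue
            assert np.isclose(exposed_boundary_voxels(m), ebv_oracle(m),
                              atol=1e-9)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            exposed_boundary_voxels(np.zeros((3, 3, 3), bool))


class TestDiscordantVoxels:
    def test_identical_masks(self, rng):
        m = rng.random((6, 6, 6)) < 0.4
        m[0, 0, 0] = True
        assert discordant_voxels([m, m, m]) == 0.0

    def test_disjoint_masks_fully_discordant(self):
        a = np.zeros((4, 4, 4), bool)
        b = np.zeros((4, 4, 4), bool)
        a.ravel()[:8] = True
        b.ravel()[8:16] = True
        assert discordant_voxels([a, b]) == 100.0

    def test_single_flipped_voxel(self, rng):
        m = rng.random((6, 6, 6)) < 0.4
        m[0, 0, 0] = True
        m2 = m.copy()
        m2[3, 3, 3] = ~m2[3, 3, 3]
        union = int((m | m2).sum())
        assert np.isclose(discordant_voxels([m, m, m2]), 100.0 / union)

    def test_gross_failure_frame_increases_dv(self, rng):
        m = rng.random((6, 6, 6)) < 0.4
        m[0, 0, 0] = True
        baseline = discordant_voxels([m, m, m])
        failure = np.ones((6, 6, 6), bool)
        assert discordant_voxels([m, m, failure]) > baseline

    def test_validation_errors(self):
        m = np.ones((3, 3, 3), bool)
        with pytest.raises(ValueError):
            discordant_voxels([m])
        with pytest.raises(ValueError):
            discordant_voxels([np.zeros((3, 3, 3), bool)] * 2)


def test_evaluate_masks_report_fields(rng):
    ref = np.zeros((12, 12, 12), bool)
    ref[3:9, 3:9, 3:9] = True
    pred = np.zeros((12, 12, 12), bool)
    pred[4:9, 3:9, 3:9] = True
    rep = evaluate_masks(pred, ref, GEOM)
    assert 0 < rep.dice_pct < 100
    assert rep.mean_surface_distance_mm >= 0
    assert rep.hausdorff_mm >= rep.mean_surface_distance_mm
    assert rep.volume_diff_pct == abs(rep.volume_diff_signed_pct)
    assert rep.sensitivity_pct < 100.0 and rep.specificity_pct == 100.0
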