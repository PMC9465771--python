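import dataclasses

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter, map_coordinates

from stripforge import (GrayVolume, SpatialTransform, SynthesisRanges,
                        VolumeGeometry, apply_bias_field, apply_crop,
                        apply_downsample, apply_gamma, apply_transform,
                        generate_training_pair, integrate_svf,
                        merge_to_brain_mask, sample_synthesis,
                        synthesize_intensities)
from stripforge.synth import (make_affine, sample_smooth_field,
                              generate_training_pair as gen_pair)
from stripforge.volumes import LabelMap
from stripforge import toy

RANGES = SynthesisRanges()


class TestSampling:
    def test_determinism(self):
        a = sample_synthesis(RANGES, {1, 2, 3}, 5)
        b = sample_synthesis(RANGES, {1, 2, 3}, 5)
        assert np.array_equal(a.translation_mm, b.translation_mm)
        assert a.label_params == b.label_params
        assert a.apply_crop == b.apply_crop

    def test_bounds_respected(self):
        for seed in range(200):
            s = sample_synthesis(RANGES, {1}, seed)
            assert np.all(np.abs(s.translation_mm) <= 50.0)
            assert np.all(np.abs(s.rotation_deg) <= 45.0)
            assert np.all((80.0 <= s.scale_pct) & (s.scale_pct <= 120.0))
            assert 8.0 <= s.svf_spacing_mm <= 16.0
            assert 0.0 <= s.svf_sd_mm <= 3.0
            assert -0.25 <= s.gamma <= 0.25
            assert np.all(s.r_per_axis >= 1.0) and np.all(s.r_per_axis <= 5.0)
            for mu, sd in s.label_params.values():
                assert 0.0 <= mu <= 1.0 and 0.0 <= sd <= 0.1

    def test_empty_label_set_rejected(self):
        with pytest.raises(ValueError):
            sample_synthesis(RANGES, set(), 0)


class TestSvfIntegration:
    geom = VolumeGeometry.isotropic(16)

    def test_zero_velocity_identity(self):
        v = np.zeros((3, 5, 5, 5))
        disp = integrate_svf(v, 4.0, steps=5, target_geometry=self.geom)
        assert not disp.any()

    def test_constant_velocity_is_translation(self):
        v = np.zeros((3, 5, 5, 5))
        v[0] = 2.0
        v[2] = -1.5
        disp = integrate_svf(v, 4.0, steps=5, target_geometry=self.geom)
        assert np.allclose(disp[0], 2.0, atol=1e-9)
        assert np.allclose(disp[1], 0.0, atol=1e-9)
        assert np.allclose(disp[2], -1.5, atol=1e-9)

    def test_agrees_with_repeated_composition_oracle(self, rng):
        # a small smooth velocity, as produced by coarse-grid sampling
        v = rng.normal(0, 0.8, size=(3, 16, 16, 16))
        v = np.stack([gaussian_filter(v[c], 2.0) for c in range(3)])
        disp = integrate_svf(v, 1.0, steps=5)
        # oracle: compose the v/32 flow 32 times sequentially
        small = v / 32.0
        phi = np.zeros_like(v)
        ident = np.indices((16, 16, 16), dtype=float)
        for _ in range(32):
            coords = ident + phi
            step = np.stack([
                map_coordinates(small[c], coords, order=1, mode="nearest")
                for c in range(3)
            ])
            phi = phi + step
        assert np.abs(disp - phi).max() < 0.1


class TestApplyTransform:
    def make_map(self):
        labels = np.zeros((16, 16, 16), np.int32)
        labels[4:10, 5:11, 6:12] = 1
        labels[6:8, 7:9, 8:10] = 2
        geom = VolumeGeometry.isotropic(16)
        return LabelMap(labels, geom, frozenset({1, 2}), frozenset())

    def identity_transform(self, geom):
        return SpatialTransform(np.eye(4), None, None,
                                np.zeros((3, *geom.shape)))

    def test_identity(self):
        s = self.make_map()
        out = apply_transform(s, self.identity_transform(s.geometry))
        assert np.array_equal(out.labels, s.labels)

    def test_integer_translation_shifts_exactly(self):
        s = self.make_map()
        A = np.eye(4)
        A[:3, 3] = [3.0, 0.0, 0.0]  # +3 voxels along axis 0
        t = SpatialTransform(A, None, None, np.zeros((3, *s.geometry.shape)))
        out = apply_transform(s, t)
        assert np.array_equal(out.labels[3:], s.labels[:-3])
        assert not out.labels[:3].any()  # background fill

    def test_warped_label_set_contained(self, rng):
        s = self.make_map()
        for seed in range(5):
            sample = sample_synthesis(RANGES.scaled_for_fov(16.0),
                                      {1, 2}, seed)
            from stripforge.synth import build_transform
            t = build_transform(sample, s.geometry, seed)
            out = apply_transform(s, t)
            assert set(np.unique(out.labels)) <= {0, 1, 2}

    def test_affine_scaling_scales_mask_volume(self):
        labels = np.zeros((64, 64, 64), np.int32)
        idx = np.indices((64, 64, 64), dtype=float)
        r2 = sum((idx[a] - 31.5) ** 2 for a in range(3))
        labels[r2 <= 20.0 ** 2] = 1
        geom = VolumeGeometry.isotropic(64)
        s = LabelMap(labels, geom, frozenset({1}), frozenset())
        sample = sample_synthesis(RANGES, {1}, 0)
        sample.scale_pct = np.array([120.0, 120.0, 120.0])
        sample.rotation_deg = np.zeros(3)
        sample.translation_mm = np.zeros(3)
        A = make_affine(sample, geom)
        t = SpatialTransform(A, None, None, np.zeros((3, 64, 64, 64)))
        out = apply_transform(s, t)
        ratio = out.labels.sum() / s.labels.sum()
        assert abs(ratio - 1.2 ** 3) / 1.2 ** 3 < 0.05


class TestIntensitySynthesis:
    def make_map(self):
        labels = np.zeros((12, 12, 12), np.int32)
        labels[:6] = 1
        labels[6:, :, :6] = 2
        geom = VolumeGeometry.isotropic(12)
        return LabelMap(labels, geom, frozenset({1, 2}), frozenset())

    def sample_with(self, params):
        s = sample_synthesis(RANGES, set(params), 0)
        s.label_params = params
        return s

    def test_zero_sd_piecewise_constant(self):
        s = self.make_map()
        x = synthesize_intensities(s, self.sample_with({1: (0.3, 0.0),
                                                        2: (0.9, 0.0)}))
        assert np.all(x.data[s.labels == 1] == 0.3)
        assert np.all(x.data[s.labels == 2] == 0.9)
        assert np.all(x.data[s.labels == 0] == 0.0)
        assert len(np.unique(x.data)) == 3

    def test_sample_mean_near_label_mean(self):
        labels = np.ones((16, 16, 16), np.int32)
        geom = VolumeGeometry.isotropic(16)
        s = LabelMap(labels, geom, frozenset({1}), frozenset())
        x = synthesize_intensities(s, self.sample_with({1: (0.5, 0.1)}),
                                   seed=3)
        se = 0.1 / np.sqrt(labels.size)
        assert abs(x.data.mean() - 0.5) < 3 * se

    def test_missing_label_params_rejected(self):
        s = self.make_map()
        with pytest.raises(ValueError):
            synthesize_intensities(s, self.sample_with({1: (0.5, 0.0)}))


class TestCorruptions:
    geom = VolumeGeometry.isotropic(16)

    def smooth_volume(self, rng):
        return GrayVolume(gaussian_filter(rng.random((16, 16, 16)), 2.0),
                          self.geom)

    def test_bias_sd_zero_identity(self, rng):
        x = self.smooth_volume(rng)
        out = apply_bias_field(x, 8.0, 0.0, seed=0)
        assert np.array_equal(out.data, x.data)

    def test_bias_positive_and_invertible(self, rng):
        x = GrayVolume(0.1 + rng.random((16, 16, 16)), self.geom)
        out = apply_bias_field(x, 8.0, 0.4, seed=9)
        assert np.all(out.data > 0)
        field = sample_smooth_field(self.geom, 8.0, 0.4, seed=9)
        assert np.allclose(np.log(out.data / x.data), field, atol=1e-12)

    def test_gamma(self, rng):
        x = self.smooth_volume(rng)
        assert np.allclose(apply_gamma(x, 0.0).data, x.data)
        fixed = GrayVolume(np.tile([0.0, 1.0], 2048).reshape(16, 16, 16),
                           self.geom)
        for g in (-0.2, 0.2):
            assert np.array_equal(apply_gamma(fixed, g).data, fixed.data)
        quarter = GrayVolume(np.full((16, 16, 16), 0.25), self.geom)
        assert np.allclose(apply_gamma(quarter, np.log(2.0)).data, 0.0625)
        with pytest.raises(ValueError):
            apply_gamma(GrayVolume(np.full((16, 16, 16), -1.0), self.geom), 0.1)

    def test_crop(self, rng):
        x = GrayVolume(np.ones((16, 16, 16)), self.geom)
        out = apply_crop(x, [0.0, 0.0, 0.0], [0, 0, 0])
        assert np.array_equal(out.data, x.data)
        out = apply_crop(x, [0.0, 0.0, 10.0], [0, 0, 1])
        assert not out.data[:, :, -10:].any()
        assert out.data[:, :, :-10].all()
        assert out.data.shape == (16, 16, 16)
        counts = [int(apply_crop(x, [e, 0, 0], [0, 0, 0]).data.sum())
                  for e in (0.0, 4.0, 8.0, 12.0)]
        assert counts == sorted(counts, reverse=True)
        with pytest.raises(ValueError):
            apply_crop(x, [16.0, 0.0, 0.0], [0, 0, 0])

    def test_downsample_blur_sigma_is_quarter_r(self, rng):
        x = self.smooth_volume(rng)
        # r = 1: no resampling, pure sigma = 0.25 blur
        out = apply_downsample(x, [1.0, 1.0, 1.0])
        assert np.allclose(out.data, gaussian_filter(x.data, 0.25,
                                                     mode="nearest"))
        assert np.abs(out.data - x.data).max() < 0.05
        # r = 4: sigma = 1.0 exactly, then down/up resampling
        from scipy.ndimage import zoom
        out4 = apply_downsample(x, [4.0, 4.0, 4.0])
        blurred = gaussian_filter(x.data, 1.0, mode="nearest")
        down = zoom(blurred, 4 / 16, order=1, mode="nearest", grid_mode=True)
        up = zoom(down, 16 / 4, order=1, mode="nearest", grid_mode=True)
        assert np.allclose(out4.data, up)

    def test_downsample_mass_conservation(self):
        # smooth interior-supported bump
        data = np.zeros((16, 16, 16))
        data[4:12, 4:12, 4:12] = 1.0
        data = gaussian_filter(data, 1.0)
        x = GrayVolume(data, self.geom)
        out = apply_downsample(x, [2.0, 1.0, 3.0])
        assert abs(out.data.sum() - data.sum()) / data.sum() < 0.01


class TestTrainingPair:
    def test_bitwise_determinism(self, toy_label_map):
        a = generate_training_pair(toy_label_map, toy.toy_ranges(), 99)
        b = generate_training_pair(toy_label_map, toy.toy_ranges(), 99)
        assert np.array_equal(a[0].data, b[0].data)
        assert np.array_equal(a[1], b[1])
        assert np.array_equal(a[2].values, b[2].values)

    def test_targets_consistent_with_warped_labels(self, toy_label_map):
        from stripforge.sdt_loss import signed_distance
        x, y_hat, d_hat, details = gen_pair(
            toy_label_map, toy.toy_ranges(), 123, return_details=True)
        s_t = details["warped_labels"]
        assert np.array_equal(y_hat, merge_to_brain_mask(s_t))
        assert np.array_equal(
            d_hat.values,
            signed_distance(y_hat, toy_label_map.geometry).values)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_image_normalized_and_finite(self, toy_label_map, seed):
        x, y_hat, d_hat = generate_training_pair(
            toy_label_map, toy.toy_ranges(), seed)
        assert np.all(np.isfinite(x.data))
        assert x.data.min() >= 0.0 and x.data.max() <= 1.0
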