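"""Augmentation: identity draws, geometric consistency, sampling oracles."""

import numpy as np
import pytest

from renalswin.augment import (AugmentationSpec, GeometricDraw, add_noise,
                               apply_geometric, lesion_aware_oversample,
                               mixup_pair, random_geometric, random_intensity)
from renalswin.io import ImageSlice, SegMask
from renalswin.manifest import DatasetManifest, ManifestRecord


def _identity_spec():
    return AugmentationSpec(rotation_deg=0.0, hflip=False, translate_frac=0.0,
                            scale_range=(1.0, 1.0), brightness_frac=0.0,
                            contrast_frac=0.0, gamma_range=(1.0, 1.0),
                            gauss_noise_sigma=0.0, blur_sigma=0.0)


class TestGeometric:
    def test_identity_ranges_give_identity(self, rng, paired_mask):
        img = ImageSlice(rng.uniform(0, 1, (32, 32)))
        out_img, out_mask, draw = random_geometric(img, paired_mask,
                                                   _identity_spec(), rng)
        np.testing.assert_allclose(out_img.pixels, img.pixels, atol=1e-12)
        np.testing.assert_array_equal(out_mask.labels, paired_mask.labels)

    def test_mask_label_subset(self, rng, paired_mask):
        img = ImageSlice(rng.uniform(0, 1, (32, 32)))
        spec = AugmentationSpec()
        for _ in range(10):
            _, out_mask, _ = random_geometric(img, paired_mask, spec, rng)
            assert set(np.unique(out_mask.labels)) <= set(np.unique(paired_mask.labels))

    def test_180_rotation_is_involution(self, rng):
        px = rng.uniform(0, 1, (33, 33))  # odd side: exact center pixel
        draw = GeometricDraw(angle_deg=180.0, flip=False, translate=(0, 0), scale=1.0)
        once = apply_geometric(px, draw, order=0)
        twice = apply_geometric(once, draw, order=0)
        np.testing.assert_allclose(twice, px, atol=1e-9)

    def test_draw_replays_identically_on_mask(self, rng, paired_mask):
        img = ImageSlice(rng.uniform(0, 1, (32, 32)))
        _, out_mask, draw = random_geometric(img, paired_mask,
                                             AugmentationSpec(), rng)
        replay = np.round(apply_geometric(paired_mask.labels, draw,
                                          order=0, cval=0)).astype(int)
        np.testing.assert_array_equal(out_mask.labels, replay)


class TestIntensity:
    def test_identity_parameters(self, rng):
        img = ImageSlice(rng.uniform(0, 1, (16, 16)))
        out = random_intensity(img, _identity_spec(), rng)
        np.testing.assert_allclose(out.pixels, img.pixels, atol=1e-12)

    def test_gamma_two_on_half(self):
        img = ImageSlice(np.full((8, 8), 0.5))
        spec = AugmentationSpec(brightness_frac=0.0, contrast_frac=0.0,
                                gamma_range=(2.0, 2.0))
        out = random_intensity(img, spec, np.random.default_rng(0))
        np.testing.assert_allclose(out.pixels, 0.25)

    def test_rank_order_preserved_without_gamma(self, rng):
        img = ImageSlice(np.sort(rng.uniform(0.2, 0.8, 256)).reshape(16, 16))
        spec = AugmentationSpec(gamma_range=(1.0, 1.0))
        out = random_intensity(img, spec, rng).pixels
        assert np.all(np.diff(out.ravel()) >= -1e-12)

    def test_requires_unit_range(self, rng):
        with pytest.raises(ValueError):
            random_intensity(ImageSlice(np.full((8, 8), 3.0)),
                             AugmentationSpec(), rng)


class TestNoise:
    def test_zero_sigmas_identity(self, rng):
        img = ImageSlice(rng.uniform(0, 1, (16, 16)))
        out = add_noise(img, _identity_spec(), rng)
        np.testing.assert_array_equal(out.pixels, img.pixels)

    def test_noise_std_monte_carlo(self):
        # pre-clip noise std on a mid-gray image, 10^6 pixels
        rng = np.random.default_rng(3)
        img = ImageSlice(np.full((1000, 1000), 0.5))
        spec = AugmentationSpec(gauss_noise_sigma=0.01, blur_sigma=0.0)
        out = add_noise(img, spec, rng).pixels
        resid = out - 0.5
        se = 0.01 / np.sqrt(2 * (10 ** 6 - 1))
        assert abs(resid.std() - 0.01) < 4 * se

    def test_blur_of_constant_is_constant(self, rng):
        img = ImageSlice(np.full((16, 16), 0.3))
        spec = AugmentationSpec(gauss_noise_sigma=0.0, blur_sigma=0.5)
        np.testing.assert_allclose(add_noise(img, spec, rng).pixels, 0.3, atol=1e-12)


class TestMixup:
    def test_forced_lambda_one_returns_first(self, rng):
        a = (rng.uniform(size=(8, 8)), np.array([1.0, 0, 0, 0]))
        b = (rng.uniform(size=(8, 8)), np.array([0, 1.0, 0, 0]))
        img, lab, lam = mixup_pair(a, b, lam=1.0)
        np.testing.assert_array_equal(img, a[0])
        np.testing.assert_array_equal(lab, a[1])
        assert lam == 1.0

    def test_half_mix_of_constants(self):
        a = (np.zeros((4, 4)), np.array([1.0, 0]))
        b = (np.ones((4, 4)), np.array([0, 1.0]))
        img, lab, _ = mixup_pair(a, b, lam=0.5)
        np.testing.assert_allclose(img, 0.5)
        np.testing.assert_allclose(lab, [0.5, 0.5])

    def test_lambda_mean_is_half(self):
        rng = np.random.default_rng(11)
        lams = [mixup_pair((np.zeros((2, 2)), np.zeros(2)),
                           (np.ones((2, 2)), np.ones(2)),
                           alpha=0.2, rng=rng)[2] for _ in range(10 ** 4)]
        # Beta(a, a) is symmetric: mean 1/2, var = 1/(4(2a+1))
        se = np.sqrt(1 / (4 * 1.4) / 10 ** 4)
        assert abs(np.mean(lams) - 0.5) < 4 * se

    def test_label_sums_to_one_for_any_lambda(self, rng):
        a = (np.zeros((2, 2)), np.array([1.0, 0, 0]))
        b = (np.ones((2, 2)), np.array([0, 0, 1.0]))
        for _ in range(20):
            _, lab, _ = mixup_pair(a, b, alpha=0.2, rng=rng)
            assert lab.sum() == pytest.approx(1.0, abs=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mixup_pair((np.zeros((4, 4)), np.zeros(2)),
                       (np.zeros((5, 5)), np.zeros(2)), lam=0.5)


class TestOversampling:
    def _manifest(self, counts):
        recs = [ManifestRecord(f"{c}_{i}.png", c, "train")
                for c, n in counts.items() for i in range(n)]
        return DatasetManifest(recs)

    def test_balanced_no_small_lesions_uniform(self):
        m = self._manifest({"cyst": 4, "normal": 4, "stone": 4, "tumor": 4})
        areas = {r.image_path: 1000.0 for r in m.records}
        w = lesion_aware_oversample(m, areas, AugmentationSpec(), 64 * 64)
        np.testing.assert_allclose(w, 1.0 / 16)

    def test_rare_class_gets_inverse_frequency(self):
        m = self._manifest({"cyst": 8, "normal": 8, "stone": 4, "tumor": 8})
        areas = {r.image_path: 1000.0 for r in m.records}
        w = lesion_aware_oversample(m, areas, AugmentationSpec(), 64 * 64)
        w_stone = w[[r.class_label == "stone" for r in m.records]][0]
        w_cyst = w[[r.class_label == "cyst" for r in m.records]][0]
        assert w_stone == pytest.approx(2 * w_cyst)

    def test_small_lesions_boosted(self):
        m = self._manifest({"cyst": 2, "normal": 2, "stone": 2, "tumor": 2})
        areas = {r.image_path: (5.0 if r.class_label == "stone" else 500.0)
                 for r in m.records}
        spec = AugmentationSpec(oversample_boost=3.0)
        w = lesion_aware_oversample(m, areas, spec, 64 * 64)
        w_stone = w[[r.class_label == "stone" for r in m.records]][0]
        w_cyst = w[[r.class_label == "cyst" for r in m.records]][0]
        assert w_stone == pytest.approx(3 * w_cyst)

    def test_sampling_equalizes_class_proportions(self):
        rng = np.random.default_rng(1)
        m = self._manifest({"cyst": 30, "normal": 10, "stone": 5, "tumor": 15})
        areas = {r.image_path: 1000.0 for r in m.records}
        w = lesion_aware_oversample(m, areas, AugmentationSpec(), 64 * 64)
        draws = rng.choice(len(m), size=10 ** 5, p=w)
        labels = np.array([m.records[i].class_label for i in draws])
        for c in ("cyst", "normal", "stone", "tumor"):
            assert np.mean(labels == c) == pytest.approx(0.25, abs=0.01)
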