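"""Gray conversion, Gaussian denoising, Otsu binarization, impurity removal."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from skimage.filters import threshold_otsu as sk_otsu

from grainsight.preprocess import (
    DegenerateHistogramError,
    binarize_otsu,
    foreground_mask,
    gaussian_denoise,
    otsu_threshold_from_hist,
    remove_small_components,
    to_gray,
)
from grainsight.synthetic_scenes import MultiChannelImage, SceneSpec, generate_scene
from conftest import min_area_of
from oracles import gaussian_kernel_1d, otsu_bruteforce


def _image(planes):
    return MultiChannelImage(np.dstack(planes).astype(np.uint8))


class TestToGray:
    def test_selector_weight_returns_plane(self):
        rng = np.random.default_rng(0)
        planes = [rng.integers(0, 256, (8, 8)) for _ in range(5)]
        img = _image(planes)
        assert np.array_equal(to_gray(img, (0, 0, 0, 1, 0)), img.planes[..., 3])

    def test_convexity_on_constant_planes(self):
        img = _image([np.full((4, 4), 100)] * 5)
        assert (to_gray(img, (0.2, 0.2, 0.2, 0.2, 0.2)) == 100).all()

    def test_arithmetic_mean(self):
        img = _image([np.full((4, 4), v) for v in (60, 120, 180, 0, 0)])
        gray = to_gray(img, (1 / 3, 1 / 3, 1 / 3, 0, 0))
        assert (gray == 120).all()

    def test_invalid_weights(self):
        img = _image([np.zeros((2, 2))] * 5)
        with pytest.raises(ValueError):
            to_gray(img, (1, 1, 0, 0, 0))
        with pytest.raises(ValueError):
            to_gray(img, (-0.5, 1.5, 0, 0, 0))
        with pytest.raises(ValueError):
            to_gray(img, (1.0, 0, 0))


class TestGaussianDenoise:
    def test_sigma_zero_is_identity(self):
        g = np.random.default_rng(1).integers(0, 256, (10, 10)).astype(np.uint8)
        assert np.array_equal(gaussian_denoise(g, 0), g)

    def test_dc_preservation(self):
        g = np.full((12, 12), 77, dtype=np.uint8)
        assert (gaussian_denoise(g, 2.0) == 77).all()

    def test_impulse_center_equals_kernel_weight(self):
        """A single 255 pixel: the filtered center equals 255 times the
        squared central weight of the truncated sampled Gaussian."""
        g = np.zeros((15, 15), dtype=np.uint8)
        g[7, 7] = 255
        out = gaussian_denoise(g, 1.0)
        kernel = gaussian_kernel_1d(1.0)
        expected = int(np.floor(255 * kernel[len(kernel) // 2] ** 2 + 0.5))
        assert out[7, 7] == expected

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            gaussian_denoise(np.zeros((4, 4), dtype=np.uint8), -1.0)


class TestOtsu:
    def test_bimodal_extreme(self):
        g = np.zeros((10, 10), dtype=np.uint8)
        g[:, 5:] = 255
        mask, t = binarize_otsu(g, "dark_foreground")
        assert 0 <= t < 255
        assert mask.sum() == 50

    def test_polarity_complement(self):
        g = np.random.default_rng(3).integers(0, 256, (20, 20)).astype(np.uint8)
        dark, t1 = binarize_otsu(g, "dark_foreground")
        bright, t2 = binarize_otsu(g, "bright_foreground")
        assert t1 == t2
        assert np.array_equal(dark, ~bright)

    def test_constant_image_degenerate(self):
        with pytest.raises(DegenerateHistogramError):
            binarize_otsu(np.full((5, 5), 9, dtype=np.uint8))

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_bruteforce_on_random_histograms(self, seed):
        rng = np.random.default_rng(seed)
        hist = rng.integers(0, 50, size=256)
        if np.count_nonzero(hist) < 2:
            hist[[3, 200]] = 5
        assert otsu_threshold_from_hist(hist) == otsu_bruteforce(hist)

    def test_cross_check_against_skimage(self):
        rng = np.random.default_rng(5)
        g = np.clip(
            np.concatenate([rng.normal(80, 10, 500), rng.normal(190, 12, 500)]),
            0, 255,
        ).astype(np.uint8).reshape(25, 40)
        _, t = binarize_otsu(g)
        assert abs(t - sk_otsu(g)) <= 1  # bin-center convention differs


class TestRemoveSmall:
    def _mask(self):
        m = np.zeros((40, 60), dtype=bool)
        m[5:30, 5:25] = True  # 500 px blob
        m[2, 40] = m[35, 50] = True
        m[10, 45:47] = True  # 2 px speck
        return m

    def test_specks_removed_blob_kept(self):
        out = remove_small_components(self._mask(), 50)
        assert out.sum() == 500

    def test_min_area_zero_identity(self):
        m = self._mask()
        assert np.array_equal(remove_small_components(m, 0), m)

    def test_min_area_above_everything_empties(self):
        assert not remove_small_components(self._mask(), 10_000).any()

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(0, 30))
    def test_idempotent_and_monotone(self, seed, min_area):
        m = np.random.default_rng(seed).random((30, 30)) < 0.4
        once = remove_small_components(m, min_area)
        twice = remove_small_components(once, min_area)
        assert np.array_equal(once, twice)
        assert not (once & ~m).any()  # output foreground subset of input


def test_foreground_recovery_within_5pct(small_scene):
    """Denoise-then-binarize recovers the rendered silhouette area."""
    spec, image, gt = small_scene
    mask, _, _ = foreground_mask(image, min_area=min_area_of(spec))
    true_fg = (gt.instance_mask > 0).sum()
    assert abs(mask.sum() - true_fg) / true_fg < 0.05
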