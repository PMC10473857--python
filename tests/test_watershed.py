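"""Gradient computation, minima suppression, and watershed flooding."""

import dataclasses
import warnings

import numpy as np
import pytest
from scipy import ndimage as ndi
from scipy.ndimage import gaussian_filter

from grainsight.preprocess import foreground_mask, gaussian_denoise
from grainsight.regions import TriageResult, label_regions
from grainsight.synthetic_scenes import SceneSpec, generate_scene
from grainsight.watershed import (
    absorb_ribbon_basins,
    compute_gradient,
    difference_gradient,
    flood_labels,
    split_adhered,
    suppress_minima,
    watershed_flood,
)
from conftest import min_area_of
from oracles import flood_bruteforce, partitions_match

S8 = np.ones((3, 3), dtype=bool)


class TestDifferenceGradient:
    def test_constant_image_zero(self):
        assert (difference_gradient(np.full((6, 6), 9)) == 0).all()

    def test_three_four_five_substitution(self):
        f = np.array([[0, 7], [6, 10]], dtype=float)
        g = difference_gradient(f)
        assert g[1, 1] == 5.0  # sqrt((10-7)^2 + (10-6)^2)

    def test_vertical_step_edge(self):
        f = np.zeros((5, 8))
        f[:, 4:] = 255
        g = difference_gradient(f)
        assert (g[:, 4] == 255).all()
        g[:, 4] = 0
        assert (g == 0).all()

    def test_replicated_border(self):
        f = np.arange(16).reshape(4, 4).astype(float)
        g = difference_gradient(f)
        assert g[0, 0] == 0.0  # both differences vanish across the border

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            difference_gradient(np.zeros((1, 5)))


class TestSuppressMinima:
    def test_identity_when_already_above_threshold(self):
        g = np.full((5, 5), 20.0)
        g[2, 2] = 30.0
        out, t = suppress_minima(g, mode="fixed", threshold=10.0)
        assert np.array_equal(out, g) and t == 10.0

    def test_deep_basins_survive_clamping(self):
        g = np.full((5, 9), 5.0)
        g[:, 4] = 100.0  # high ridge between two deep basins
        out, t = suppress_minima(g, mode="fixed", threshold=8.0)
        lab = flood_labels(out, np.ones_like(g, dtype=bool))
        assert len(np.unique(lab[lab > 0])) == 2

    def test_degenerate_gradient_warns_and_passes_through(self):
        g = np.full((4, 4), 3.0)
        with warnings.catch_warnings(record=True) as rec:
            warnings.simplefilter("always")
            out, t = suppress_minima(g, mode="otsu")
        assert t is None and np.array_equal(out, g)
        assert any("degenerate" in str(w.message) for w in rec)


def _two_disc_scene(noise_seed=0):
    """Two overlapping shaded discs (r = 25, centers 40 px apart) with a
    contact seam on the known perpendicular bisector at x = 60."""
    H = W = 120
    yy, xx = np.mgrid[0:H, 0:W].astype(float)
    d1 = np.hypot(yy - 60.0, xx - 40.0) / 25.0
    d2 = np.hypot(yy - 60.0, xx - 80.0) / 25.0
    img = np.full((H, W), 230.0)
    for d in (d1, d2):
        inside = d <= 1
        val = 150 + 22 * np.clip(d, 0, 1) ** 6
        img[inside] = np.minimum(img[inside], val[inside])
    s = xx - 60.0
    wedge = (d1 <= 1 + 0.1) & (d2 <= 1 + 0.1)
    img += np.maximum((188 - img) * np.exp(-0.5 * (np.abs(s) - 2.2) ** 2) * wedge, 0)
    img += np.minimum((90 - img) * np.exp(-0.5 * (s / 0.8) ** 2) * wedge, 0)
    img = gaussian_filter(img, 0.5)
    img += np.random.default_rng(noise_seed).normal(0, 4, img.shape)
    gray = np.floor(np.clip(img, 0, 255) + 0.5).astype(np.uint8)
    return gray, (d1 <= 1) | (d2 <= 1), xx


class TestWatershedFlood:
    def test_single_disc_one_segment(self):
        gray, _, _ = _two_disc_scene()
        yy, xx = np.mgrid[0:120, 0:120].astype(float)
        solo = np.hypot(yy - 60.0, xx - 40.0) <= 20  # left disc body only
        den = gaussian_denoise(gray, 1.0)
        grad = compute_gradient(den)
        clamped, _ = suppress_minima(grad, mask=solo)
        (region,) = label_regions(solo)
        result = watershed_flood(clamped, region)
        assert result.n_segments == 1

    def test_one_pixel_region(self):
        m = np.zeros((3, 3), dtype=bool)
        m[1, 1] = True
        (region,) = label_regions(m)
        result = watershed_flood(np.zeros((3, 3)), region)
        assert result.n_segments == 1 and not result.watershed_lines.any()

    def test_two_overlapping_discs_split_on_bisector(self):
        """Clamped flooding recovers two basins whose interface lies within
        3 px of the analytic perpendicular bisector."""
        gray, mask, xx = _two_disc_scene()
        den = gaussian_denoise(gray, 1.0)
        clamped, _ = suppress_minima(compute_gradient(den), mask=mask)
        lab = flood_labels(clamped, mask)
        absorb_ribbon_basins(lab)
        ids, counts = np.unique(lab[lab > 0], return_counts=True)
        big = ids[counts >= 40]
        assert len(big) == 2
        d1b = ndi.binary_dilation(lab == big[0], S8, iterations=3)
        d2b = ndi.binary_dilation(lab == big[1], S8, iterations=3)
        interface = d1b & d2b
        assert interface.any()
        assert np.abs(xx[interface] - 60.0).max() <= 3.0

    def test_unclamped_flood_oversegments(self):
        """Without minima suppression the noisy clump floods into many
        spurious basins; clamping removes them (directional control)."""
        gray, mask, _ = _two_disc_scene()
        den = gaussian_denoise(gray, 1.0)
        grad = compute_gradient(den)
        naive = flood_labels(grad, mask)
        clamped, _ = suppress_minima(grad, mask=mask)
        lab = flood_labels(clamped, mask)
        n_naive = len(np.unique(naive[naive > 0]))
        n_clamped = len(np.unique(lab[lab > 0]))
        assert n_naive > n_clamped
        assert n_naive > 2

    def test_partition_contract(self):
        """Submasks are disjoint and, with line pixels, tile the region."""
        rng = np.random.default_rng(11)
        grad = rng.integers(0, 6, (30, 30)).astype(float)
        mask = rng.random((30, 30)) < 0.8
        mask[0] = False
        (region,) = label_regions(np.ones((30, 30), dtype=bool))
        lab = flood_labels(grad, mask)
        assert ((lab != 0) == mask).all()
        covered = np.zeros_like(mask)
        for k in np.unique(lab[lab > 0]):
            sub = lab == k
            assert not (covered & sub).any()
            covered |= sub
        assert ((covered | (lab == -1)) == mask).all()

    def test_matches_bruteforce_flood(self):
        """Basin partition equals an independent fixed-point flood, up to
        label permutation, on random small patches."""
        rng = np.random.default_rng(7)
        for _ in range(10):
            h, w = rng.integers(8, 41, size=2)
            grad = rng.integers(0, 8, size=(h, w)).astype(float)
            mask = rng.random((h, w)) < 0.85
            assert partitions_match(flood_labels(grad, mask),
                                    flood_bruteforce(grad, mask))


class TestSplitAdhered:
    def test_singles_pass_through_unchanged(self):
        spec = SceneSpec(width=512, height=512, n_grains=10,
                         adhesion_prob=0.0, seed=9)
        image, _ = generate_scene(spec)
        mask, gray, _ = foreground_mask(image, min_area=min_area_of(spec))
        regs = label_regions(mask)
        tri = TriageResult(singles=list(regs), adhered=[],
                           threshold_used=0.55, area_gate_used=np.inf)
        final, report = split_adhered(gray, tri, min_area=min_area_of(spec))
        assert final == regs
        assert report.n_adhered == 0 and not report.unsplit_regions

    def test_pair_clump_yields_two_masks(self):
        spec = SceneSpec(width=220, height=220, n_grains=2,
                         adhesion_prob=1.0, seed=1003, impurity_count=0)
        image, gt = generate_scene(spec)
        mask, gray, _ = foreground_mask(image, min_area=min_area_of(spec))
        regs = label_regions(mask)
        assert len(regs) == 1
        tri = TriageResult([], regs, 0.55, np.inf)
        final, report = split_adhered(gray, tri, min_area=min_area_of(spec))
        assert len(final) == 2
        assert report.n_segments_per_adhered == [2]

    def test_unsplittable_region_passes_through_flagged(self):
        """A region over a flat gray field cannot split; it is returned
        whole and flagged in the report."""
        gray = np.full((40, 40), 100, dtype=np.uint8)
        m = np.zeros((40, 40), dtype=bool)
        m[10:30, 8:32] = True
        (region,) = label_regions(m)
        tri = TriageResult([], [region], 0.55, np.inf)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            final, report = split_adhered(gray, tri, min_area=10)
        assert final == [region]
        assert report.unsplit_regions == [region.label]
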