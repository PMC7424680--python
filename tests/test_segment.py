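"""Rosette segmentation operators and pipeline."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from skimage import color as skcolor

from dapd.evaluate import confusion_counts, segmentation_metrics
from dapd.fixtures import RosetteSpec, generate_rosette_image
from dapd.segment import (SegFeatures, SegmentConfig, consensus_mask,
                          enhance_contrast, green_index, hue_cluster_mask,
                          kmeans_background_removal, otsu_binarize,
                          repair_oversegmentation, segment_rosette,
                          select_algorithm)


def brute_force_otsu(levels: np.ndarray) -> int:
    """Exhaustive between-class-variance maximizer (lowest-threshold ties)."""
    values = levels.ravel().astype(float)
    best_t, best_var = 0, -1.0
    for t in range(int(values.max()) + 1):
        c0, c1 = values[values <= t], values[values > t]
        if c0.size == 0 or c1.size == 0:
            continue
        w0, w1 = c0.size / values.size, c1.size / values.size
        var = w0 * w1 * (c0.mean() - c1.mean()) ** 2
        if var > best_var + 1e-12:
            best_var, best_t = var, t
    return best_t


class TestGreenIndex:
    @pytest.mark.parametrize("rgb,expected", [
        ((0, 0, 0), 0),
        ((50, 100, 20), 130),
        ((255, 0, 0), 0),     # negative clipped
        ((0, 255, 0), 255),   # saturates at 8-bit ceiling
    ])
    def test_pixel_values(self, rgb, expected):
        img = np.array([[rgb]], dtype=np.uint8)
        assert green_index(img)[0, 0] == expected


class TestEnhanceContrast:
    def test_constant_image_unchanged(self):
        img = np.full((32, 32, 3), 120, dtype=np.uint8)
        out = enhance_contrast(img)
        assert np.allclose(out, 120 / 255.0, atol=1 / 255.0)

    def test_hue_channel_invariant(self, rng):
        img = rng.integers(0, 255, (40, 40, 3)).astype(np.uint8)
        out = enhance_contrast(img)
        hsv_in = skcolor.rgb2hsv(img / 255.0)
        hsv_out = skcolor.rgb2hsv(out)
        # compare circularly, only where hue is defined on both sides
        sel = (hsv_in[..., 1] > 1e-3) & (hsv_out[..., 1] > 1e-3) \
            & (hsv_out[..., 2] > 1e-3)
        d = np.abs(hsv_in[..., 0][sel] - hsv_out[..., 0][sel])
        assert np.all(np.minimum(d, 1.0 - d) < 1e-7)

    def test_low_contrast_ramp_is_stretched(self):
        ramp = np.linspace(100, 140, 64 * 64).reshape(64, 64)
        img = np.stack([ramp] * 3, axis=-1).astype(np.uint8)
        out = enhance_contrast(img)
        assert np.ptp(out) >= np.ptp(img / 255.0) - 1e-9


class TestOtsu:
    def test_separable_halves(self):
        img = np.array([[10] * 8, [200] * 8], dtype=np.uint8)
        thr, mask = otsu_binarize(img)
        assert 10 <= thr < 200
        assert mask.sum() == 8 and mask[1].all()

    def test_matches_brute_force_on_random_images(self, rng):
        for _ in range(12):
            img = np.concatenate([
                rng.normal(70, 18, 400), rng.normal(180, 25, 300)])
            img = np.clip(img, 0, 255).astype(np.uint8).reshape(20, 35)
            thr, _ = otsu_binarize(img)
            assert thr == brute_force_otsu(img)

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError):
            otsu_binarize(np.full((8, 8), 3, dtype=np.uint8))


class TestKMeans:
    def _two_color(self):
        img = np.zeros((40, 40, 3), dtype=np.uint8)
        img[...] = (120, 80, 40)          # brown background
        img[10:30, 10:30] = (40, 180, 40)  # green blob
        return img, np.zeros((40, 40), dtype=bool)

    def test_two_color_blob_recovered(self):
        img, _ = self._two_color()
        mask = kmeans_background_removal(img, k=2, seed=0)
        expected = np.zeros((40, 40), dtype=bool)
        expected[10:30, 10:30] = True
        assert np.array_equal(mask, expected)

    def test_seeded_determinism(self, rosette_six):
        _, rgb, _ = rosette_six
        a = kmeans_background_removal(rgb, k=3, seed=5)
        b = kmeans_background_removal(rgb, k=3, seed=5)
        assert np.array_equal(a, b)

    def test_k_reduced_with_warning(self):
        img, _ = self._two_color()
        with pytest.warns(UserWarning, match="distinct colors"):
            kmeans_background_removal(img, k=5, seed=0)

    def test_three_color_fixture_dice(self, rosette_six):
        _, rgb, truth = rosette_six
        mask = kmeans_background_removal(rgb, k=3, seed=1)
        m = segmentation_metrics(confusion_counts(mask, truth.mask))
        assert m.dice >= 99.0


class TestHueClusterMask:
    def test_single_blob_high_dice(self, rosette_six):
        _, rgb, truth = rosette_six
        mask = hue_cluster_mask(rgb, gamma=1.0)
        m = segmentation_metrics(confusion_counts(mask, truth.mask))
        assert m.dice >= 95.0

    def test_distant_artifact_removed(self, rosette_six):
        _, rgb, truth = rosette_six
        rgb = rgb.copy()
        rgb[2:9, 2:9] = (90, 140, 60)  # greenish blob far from the rosette
        mask = hue_cluster_mask(rgb, gamma=1.0)
        assert not mask[2:9, 2:9].any()

    def test_soil_only_crop_is_empty(self):
        spec = RosetteSpec(n_leaves=0, background="soil", noise_sd=0.0)
        rgb, _ = generate_rosette_image(spec, seed=2)
        with pytest.warns(UserWarning):
            mask = hue_cluster_mask(rgb, gamma=1.0)
        assert not mask.any()


class TestSelectAlgorithm:
    def test_rule_tree(self):
        cfg = SegmentConfig()
        assert select_algorithm(
            SegFeatures(0.001, 110.0, 80.0), cfg).method == "hue_histogram"
        assert select_algorithm(
            SegFeatures(0.4, 60.0, 5.0), cfg).method == "kmeans"
        assert select_algorithm(
            SegFeatures(0.1, 110.0, 120.0), cfg).method == "shape_analysis"


class TestConsensus:
    def test_identical_masks(self, rng):
        m = rng.random((10, 10)) > 0.5
        assert np.array_equal(consensus_mask([m, m, m]), m)

    def test_majority_and_tie(self):
        a = np.zeros((2, 2), bool)
        b = np.zeros((2, 2), bool)
        c = np.zeros((2, 2), bool)
        a[0, 0] = b[0, 0] = True      # 2/3 majority -> set
        a[1, 1] = True                # 1/3 -> unset
        assert consensus_mask([a, b, c])[0, 0]
        assert not consensus_mask([a, b, c])[1, 1]
        assert consensus_mask([a, b])[1, 1]  # 1/2 tie -> foreground

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            consensus_mask([np.zeros((2, 2), bool), np.zeros((3, 3), bool)])

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 2 ** 18 - 1), st.integers(1, 5))
    def test_bounded_by_union_and_intersection(self, bits, n):
        masks = []
        rng = np.random.default_rng(bits)
        for _ in range(n):
            masks.append(rng.random((6, 6)) > 0.5)
        out = consensus_mask(masks)
        union = np.logical_or.reduce(masks)
        inter = np.logical_and.reduce(masks)
        assert (out | union).sum() == union.sum()   # out subset of union
        assert (out & inter).sum() == inter.sum()   # out superset of inter


class TestRepair:
    def _disk(self, r=20, shape=(64, 64)):
        yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
        return np.hypot(yy - 32, xx - 32) <= r

    def test_interior_hole_filled(self):
        disk = self._disk()
        holey = disk.copy()
        holey[30:33, 30:33] = False
        out = repair_oversegmentation(holey)
        assert out[31, 31]

    def test_monotone_and_idempotent(self):
        disk = self._disk()
        notched = disk.copy()
        notched[31:34, 10:33] = False  # narrow wedge notch
        out = repair_oversegmentation(notched)
        assert (out | notched).sum() == out.sum()      # never removes fg
        again = repair_oversegmentation(out)
        assert np.array_equal(again, out)

    def test_notch_fill_improves_dice(self):
        disk = self._disk()
        notched = disk.copy()
        notched[31:34, 12:32] = False
        out = repair_oversegmentation(notched)

        def dice(m):
            return segmentation_metrics(confusion_counts(m, disk)).dice

        assert dice(out) > dice(notched)

    def test_mask_without_holes_unchanged(self):
        disk = self._disk()
        assert np.array_equal(repair_oversegmentation(disk), disk)


class TestSegmentRosette:
    def test_fixture_dice(self, rosette_six):
        _, rgb, truth = rosette_six
        mask = segment_rosette(rgb, seed=0)
        m = segmentation_metrics(confusion_counts(mask, truth.mask))
        assert m.dice >= 90.0

    def test_soil_only_pot_empty(self):
        spec = RosetteSpec(n_leaves=0, background="soil")
        rgb, _ = generate_rosette_image(spec, seed=4)
        assert not segment_rosette(rgb, seed=1).any()

    def test_seeded_determinism(self, rosette_six):
        _, rgb, _ = rosette_six
        assert np.array_equal(segment_rosette(rgb, seed=8),
                              segment_rosette(rgb, seed=8))
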