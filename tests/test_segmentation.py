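import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from skimage.filters import threshold_otsu as sk_otsu

from conftest import brute_force_otsu
from houghctc.errors import ConfigurationError, DegenerateHistogramError
from houghctc.segmentation import (
    ExclusionRegion,
    binarize,
    combine_masks,
    manual_threshold_review,
    otsu_threshold,
    remove_artifacts,
    threshold_field_channel,
)


class TestOtsu:
    def test_two_population_plane_selects_them_apart(self):
        plane = np.array([10] * 100 + [200] * 100, np.uint8).reshape(10, 20)
        t = otsu_threshold(plane)
        assert 10 <= t <= 199
        mask = binarize(plane, t)
        np.testing.assert_array_equal(mask, (plane == 200).astype(np.uint8))
        assert t == brute_force_otsu(plane)

    def test_binary_plane_splits_at_black(self):
        plane = (np.arange(64).reshape(8, 8) % 2 * 255).astype(np.uint8)
        t = otsu_threshold(plane)
        np.testing.assert_array_equal(binarize(plane, t), (plane == 255).astype(np.uint8))

    def test_matches_brute_force_on_seeded_planes(self):
        for seed in range(10):
            plane = np.random.default_rng(seed).integers(0, 256, (32, 32)).astype(np.uint8)
            assert otsu_threshold(plane) == brute_force_otsu(plane)

    def test_agrees_with_skimage_split(self):
        # same foreground set as the library's Otsu on a clean bimodal plane
        rng = np.random.default_rng(3)
        plane = np.clip(
            np.concatenate([rng.normal(40, 6, 600), rng.normal(190, 10, 400)]), 0, 255
        ).astype(np.uint8).reshape(25, 40)
        ours = binarize(plane, otsu_threshold(plane))
        theirs = plane > sk_otsu(plane, nbins=256)
        np.testing.assert_array_equal(ours, theirs.astype(np.uint8))

    def test_constant_plane_is_degenerate(self):
        with pytest.raises(DegenerateHistogramError):
            otsu_threshold(np.full((8, 8), 50, np.uint8))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_brute_force_equivalence_property(self, seed):
        plane = np.random.default_rng(seed).integers(0, 256, (16, 16)).astype(np.uint8)
        assert otsu_threshold(plane) == brute_force_otsu(plane)


class TestBinarize:
    @pytest.mark.parametrize(
        "value,threshold,expect",
        [(50, 49, 1), (50, 50, 0), (255, 255, 0)],
        ids=["just-above", "strict-equality-excluded", "max-threshold"],
    )
    def test_strict_greater_than(self, value, threshold, expect):
        plane = np.full((4, 4), value, np.uint8)
        assert binarize(plane, threshold).min() == binarize(plane, threshold).max() == expect


class TestManualReview:
    def test_no_override_returns_otsu(self):
        plane = np.arange(64, dtype=np.uint8).reshape(8, 8)
        rep = manual_threshold_review(plane, 31)
        assert rep.threshold == 31 and not rep.override_used
        assert rep.histogram.sum() == plane.size

    def test_override_wins(self):
        plane = np.arange(64, dtype=np.uint8).reshape(8, 8)
        rep = manual_threshold_review(plane, 31, override=120)
        assert rep.threshold == 120 and rep.override_used

    def test_out_of_range_override_rejected(self):
        plane = np.arange(64, dtype=np.uint8).reshape(8, 8)
        with pytest.raises(ConfigurationError):
            manual_threshold_review(plane, 31, override=300)


class TestCombineMasks:
    @pytest.mark.parametrize("b", [0, 1])
    @pytest.mark.parametrize("g", [0, 1])
    @pytest.mark.parametrize("r", [0, 1])
    def test_truth_table(self, b, g, r):
        one = lambda v: np.full((1, 1), v, np.uint8)
        got = combine_masks(one(b), one(g), one(r))[0, 0]
        assert got == (b & g & (1 - r))

    def test_pixelwise_oracle_on_random_masks(self, rng):
        b, g, r = (rng.integers(0, 2, (32, 32)).astype(np.uint8) for _ in range(3))
        got = combine_masks(b, g, r)
        np.testing.assert_array_equal(got, (b & g & (1 - r)))

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_subset_and_disjoint_invariant(self, seed):
        rng = np.random.default_rng(seed)
        b, g, r = (rng.integers(0, 2, (16, 16)).astype(np.uint8) for _ in range(3))
        out = combine_masks(b, g, r)
        assert not np.any(out & ~b)
        assert not np.any(out & ~g)
        assert not np.any(out & r)


class TestRemoveArtifacts:
    def test_empty_region_list_is_identity(self, rng):
        mask = rng.integers(0, 2, (20, 20)).astype(np.uint8)
        np.testing.assert_array_equal(remove_artifacts(mask, []), mask)

    def test_full_rectangle_clears_everything(self):
        mask = np.ones((10, 10), np.uint8)
        out = remove_artifacts(mask, [ExclusionRegion(rect=(0, 0, 10, 10))])
        assert out.sum() == 0

    def test_one_of_two_blobs_removed(self):
        mask = np.zeros((20, 20), np.uint8)
        mask[2:5, 2:5] = 1      # blob A
        mask[12:15, 12:15] = 1  # blob B
        out = remove_artifacts(mask, [ExclusionRegion(rect=(0, 0, 8, 8))])
        assert out[2:5, 2:5].sum() == 0
        assert out[12:15, 12:15].sum() == 9

    def test_polygon_region(self):
        mask = np.ones((20, 20), np.uint8)
        tri = ExclusionRegion(polygon=[(0, 0), (0, 19), (19, 0)])
        out = remove_artifacts(mask, [tri])
        assert out[1, 1] == 0 and out[18, 18] == 1

    def test_idempotent(self, rng):
        mask = rng.integers(0, 2, (20, 20)).astype(np.uint8)
        regions = [ExclusionRegion(rect=(3, 3, 6, 6))]
        once = remove_artifacts(mask, regions)
        np.testing.assert_array_equal(remove_artifacts(once, regions), once)

    def test_out_of_bounds_region_clipped(self):
        mask = np.ones((10, 10), np.uint8)
        out = remove_artifacts(mask, [ExclusionRegion(rect=(5, 5, 50, 50))])
        assert out[:5].sum() == 50 and out[5:, 5:].sum() == 0


class TestChannelGuard:
    def test_noise_only_channel_treated_as_empty(self):
        plane = np.clip(
            np.rint(8 + np.random.default_rng(0).normal(0, 2, (64, 64))), 0, 255
        ).astype(np.uint8)
        mask, rep = threshold_field_channel(plane)
        assert rep.channel_empty and mask.sum() == 0

    def test_stained_channel_passes(self):
        plane = np.full((64, 64), 8, np.uint8)
        plane[10:30, 10:30] = 180
        mask, rep = threshold_field_channel(plane)
        assert not rep.channel_empty
        assert mask[15, 15] == 1 and mask[50, 50] == 0

    def test_manual_threshold_bypasses_guard(self):
        plane = np.clip(
            np.rint(8 + np.random.default_rng(0).normal(0, 2, (64, 64))), 0, 255
        ).astype(np.uint8)
        mask, rep = threshold_field_channel(plane, manual=6)
        assert rep.override_used and mask.sum() > 0
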