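import math

import numpy as np
import pytest

from conftest import render_disks
from houghctc.components import Component, Fate
from houghctc.errors import ConfigurationError, DimensionError
from houghctc.hough import (
    CircleDetection,
    assign_circles,
    classify_events,
    convert_sizes,
    find_circles,
    intensity_weight,
    radius_range_from_physical,
)


class TestRadiusRange:
    @pytest.mark.parametrize(
        "dmin,dmax,res,expect",
        [
            (5, 25, 0.75, (2, 10)),   # 1.875 clamps to 2; 9.375 -> 10
            (5, 25, 1.0, (2, 13)),
            (8, 20, 0.5, (2, 5)),
        ],
    )
    def test_arithmetic(self, dmin, dmax, res, expect):
        assert radius_range_from_physical(dmin, dmax, res) == expect

    def test_degenerate_range_rejected(self):
        with pytest.raises(ConfigurationError):
            radius_range_from_physical(10, 10, 0.75)


class TestIntensityWeight:
    def test_full_mask_is_identity(self, rng):
        green = rng.integers(0, 256, (10, 10)).astype(np.uint8)
        np.testing.assert_array_equal(intensity_weight(np.ones((10, 10)), green), green)

    def test_empty_mask_annihilates(self, rng):
        green = rng.integers(0, 256, (10, 10)).astype(np.uint8)
        assert intensity_weight(np.zeros((10, 10)), green).sum() == 0

    def test_restriction_to_half(self, rng):
        green = rng.integers(1, 256, (10, 10)).astype(np.uint8)
        mask = np.zeros((10, 10))
        mask[:, :5] = 1
        out = intensity_weight(mask, green)
        np.testing.assert_array_equal(out[:, :5], green[:, :5])
        assert out[:, 5:].sum() == 0

    def test_dimension_mismatch(self):
        with pytest.raises(DimensionError):
            intensity_weight(np.ones((5, 5)), np.ones((6, 5)))


class TestConvertSizes:
    def test_stated_values(self):
        d, a = convert_sizes(3, 225, 0.75)
        assert d == pytest.approx(8.0)
        assert a == pytest.approx(400.0)

    def test_zero_radius_degenerate(self):
        d, _ = convert_sizes(0, 10, 0.75)
        assert d == 0.0


class TestFindCircles:
    def test_blank_image_gives_nothing(self):
        assert find_circles(np.zeros((64, 64)), 2, 10) == []

    @pytest.mark.parametrize("radius", range(3, 11))
    def test_single_disk_detected_exactly_once(self, radius):
        img = render_disks((64, 64), [(31.0, 33.0, radius)])
        circles = find_circles(img, 2, 10)
        assert len(circles) == 1
        (c,) = circles
        assert abs(c.center[0] - 31.0) <= 1.0
        assert abs(c.center[1] - 33.0) <= 1.0
        assert abs(c.radius_px - radius) <= 1.0

    def test_overlapping_pair_resolved(self):
        img = render_disks((64, 64), [(30, 28, 5), (30, 35, 5)])
        circles = find_circles(img, 2, 10, sensitivity=0.75)
        assert len(circles) == 2
        got = sorted((c.center for c in circles), key=lambda t: t[1])
        for (gy, gx), (ty, tx) in zip(got, [(30, 28), (30, 35)]):
            assert math.hypot(gy - ty, gx - tx) <= 2.0

    def test_noiseless_multi_disk_scene_fully_recovered(self):
        truth = [(15.0, 15.0, 4), (15.0, 48.0, 6), (48.0, 15.0, 8), (48.0, 48.0, 3)]
        img = render_disks((64, 64), truth)
        circles = find_circles(img, 2, 10)
        assert len(circles) == len(truth)
        for ty, tx, tr in truth:
            best = min(circles, key=lambda c: math.hypot(c.center[0] - ty, c.center[1] - tx))
            assert math.hypot(best.center[0] - ty, best.center[1] - tx) <= 1.0
            assert abs(best.radius_px - tr) <= 1.0

    def test_sensitivity_monotone(self):
        img = render_disks(
            (96, 96),
            [(20, 20, 4), (22, 60, 5), (60, 24, 6), (70, 70, 4), (45, 45, 3)],
            blur=0.6,
            noise=2.0,
            bg=8.0,
            seed=5,
        )
        counts = [
            len(find_circles(img, 2, 10, sensitivity=s)) for s in (0.3, 0.5, 0.65, 0.8, 0.95)
        ]
        assert counts == sorted(counts)

    def test_deterministic(self):
        img = render_disks((64, 64), [(30, 28, 5), (30, 35, 5)], noise=2.0, bg=8.0, seed=9)
        a = find_circles(img, 2, 10)
        b = find_circles(img, 2, 10)
        assert [(c.center, c.radius_px, c.score) for c in a] == [
            (c.center, c.radius_px, c.score) for c in b
        ]

    def test_invalid_radius_range(self):
        with pytest.raises(ConfigurationError):
            find_circles(np.zeros((10, 10)), 5, 3)


def _comp(label, rows, cols):
    c = Component(
        label=label,
        rows=np.asarray(rows),
        cols=np.asarray(cols),
        bbox=(min(rows), min(cols), max(rows) - min(rows) + 1, max(cols) - min(cols) + 1),
        area_px=len(rows),
    )
    c.fate = Fate.CELL_MASK
    return c


def _circle(y, x, r=3.0, score=1.0):
    return CircleDetection(center=(y, x), radius_px=r, score=score)


class TestAssignment:
    def test_center_inside_blob(self):
        comp = _comp(4, [5, 5, 6, 6], [5, 6, 5, 6])
        out = assign_circles([_circle(5.4, 5.6)], [comp], (10, 10))
        assert out[0].component_label == 4

    def test_center_on_background_dropped(self):
        comp = _comp(4, [5], [5])
        assert assign_circles([_circle(1.0, 1.0)], [comp], (10, 10)) == []

    def test_two_circles_one_blob(self):
        rows, cols = zip(*[(r, c) for r in range(4, 9) for c in range(4, 9)])
        comp = _comp(7, list(rows), list(cols))
        out = assign_circles([_circle(5, 5), _circle(7, 7)], [comp], (12, 12))
        assert [c.component_label for c in out] == [7, 7]


class TestClassification:
    def test_zero_centers_component_is_rejected(self):
        comp = _comp(1, [5], [5])
        cells, clusters, rejected = classify_events([comp], [], 0.75)
        assert cells == [] and clusters == [] and rejected == [comp]

    def test_one_center_is_free_ctc(self):
        comp = _comp(1, [5], [5])
        circ = _circle(5, 5)
        circ.component_label = 1
        cells, clusters, rejected = classify_events([comp], [circ], 0.75)
        assert len(cells) == 1 and cells[0].kind == "free"
        assert clusters == [] and rejected == []

    def test_counts_per_center_multiplicity(self):
        comp1 = _comp(1, [5], [5])
        comp2 = _comp(2, [20], [20])
        c_free = _circle(5, 5)
        c_free.component_label = 1
        members = []
        for dy in range(3):
            c = _circle(20 + dy, 20, r=3.0)
            c.component_label = 2
            members.append(c)
        cells, clusters, rejected = classify_events([comp1, comp2], [c_free] + members, 0.75)
        kinds = sorted(e.kind for e in cells)
        assert kinds == ["clustered", "clustered", "clustered", "free"]
        assert len(clusters) == 1 and clusters[0].n_cells == 3
        assert rejected == []
        # diameter conversion carried through: r=3 at 0.75 px/um -> 8 um
        assert cells[0].diameter_um == pytest.approx(8.0)

    def test_cluster_area_in_physical_units(self):
        rows, cols = zip(*[(r, c) for r in range(0, 15) for c in range(0, 15)])
        comp = _comp(3, list(rows), list(cols))  # 225 px
        members = []
        for dx in (3, 9):
            c = _circle(7, dx)
            c.component_label = 3
            members.append(c)
        _, clusters, _ = classify_events([comp], members, 0.75)
        assert clusters[0].area_um2 == pytest.approx(400.0)
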