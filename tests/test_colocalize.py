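import math

import numpy as np
import pytest

from puncta_coloc.colocalize import (
    ROISpec,
    apply_roi,
    circle_overlap_area,
    circles_overlap,
    coloc_circular,
    coloc_pixel,
)
from tests.conftest import make_punctum


class TestCirclesOverlap:
    def test_concentric(self):
        assert circles_overlap(make_punctum(0, 0, 5), make_punctum(0, 0, 5))

    def test_tangent_is_not_overlap(self):
        assert not circles_overlap(make_punctum(0, 0, 3), make_punctum(7, 0, 4))

    def test_partial_overlap(self):
        assert circles_overlap(make_punctum(0, 0, 3), make_punctum(5, 0, 4))


class TestCircleOverlapArea:
    def test_identical_circles(self):
        area = circle_overlap_area(make_punctum(0, 0, 5), make_punctum(0, 0, 5))
        assert area == pytest.approx(25 * math.pi)

    def test_lens_3_4_5(self):
        # value frozen from the 10^7-sample Monte-Carlo oracle
        area = circle_overlap_area(make_punctum(0, 0, 3), make_punctum(5, 0, 4))
        assert area == pytest.approx(6.642, abs=5e-3)

    def test_containment_returns_smaller_disk(self):
        area = circle_overlap_area(make_punctum(0, 0, 1), make_punctum(2, 0, 4))
        assert area == pytest.approx(math.pi)

    def test_errors_on_disjoint(self):
        with pytest.raises(ValueError):
            circle_overlap_area(make_punctum(0, 0, 1), make_punctum(10, 0, 1))

    def test_symmetric(self, rng):
        for _ in range(20):
            r1, r2 = rng.uniform(0.5, 8, 2)
            d = float(rng.uniform(0, (r1 + r2) * 0.99))
            p1, p2 = make_punctum(0, 0, r1), make_punctum(d, 0, r2)
            assert circle_overlap_area(p1, p2) == pytest.approx(circle_overlap_area(p2, p1))
            assert 0 < circle_overlap_area(p1, p2) <= math.pi * min(r1, r2) ** 2 + 1e-12

    def test_continuous_vanishing_at_tangency(self):
        area = circle_overlap_area(make_punctum(0, 0, 5), make_punctum(10 - 1e-6, 0, 5))
        assert 0 < area < 1e-3

    @pytest.mark.parametrize("seed", range(4))
    def test_monte_carlo_oracle(self, seed):
        # light version of the geometry cross-check (10^5 points/pair)
        rng = np.random.default_rng(seed)
        for _ in range(10):
            r1, r2 = rng.uniform(0.5, 10, 2)
            d = float(rng.uniform(0, (r1 + r2) * 0.995))
            closed = circle_overlap_area(make_punctum(0, 0, r1), make_punctum(d, 0, r2))
            est = _mc_lens_area(r1, r2, d, 10**5, rng)
            assert est == pytest.approx(closed, rel=0.05)


def _mc_lens_area(r1, r2, d, n, rng):
    """Point-sampling estimate of the intersection area of two circles."""
    if d <= abs(r1 - r2):
        rs, cx = (r1, 0.0) if r1 <= r2 else (r2, d)
        x = rng.uniform(cx - rs, cx + rs, n)
        y = rng.uniform(-rs, rs, n)
        box = (2 * rs) ** 2
    else:
        x0, x1 = d - r2, r1
        ymax = min(r1, r2)
        x = rng.uniform(x0, x1, n)
        y = rng.uniform(-ymax, ymax, n)
        box = (x1 - x0) * 2 * ymax
    inside = (x**2 + y**2 <= r1**2) & ((x - d) ** 2 + y**2 <= r2**2)
    return inside.mean() * box


class TestColocCircular:
    def test_single_pair(self):
        colocs = coloc_circular([make_punctum(10, 10, 3)], [make_punctum(12, 10, 3, channel="green")])
        assert len(colocs) == 1
        assert colocs[0].overlap_area > 0
        # chord midpoint lies between the centers
        assert 10 <= colocs[0].centroid_x <= 12
        assert colocs[0].centroid_y == pytest.approx(10)

    def test_one_red_two_greens_counts_pairwise(self):
        red = [make_punctum(10, 10, 3)]
        green = [make_punctum(12, 10, 2, pid=0), make_punctum(8, 10, 2, pid=1)]
        assert len(coloc_circular(red, green)) == 2

    def test_disjoint_clouds(self):
        red = [make_punctum(5, 5, 1), make_punctum(10, 5, 1)]
        green = [make_punctum(50, 50, 1), make_punctum(60, 60, 1)]
        assert coloc_circular(red, green) == []

    def test_concentric_centroid_is_shared_center(self):
        (c,) = coloc_circular([make_punctum(7, 9, 2)], [make_punctum(7, 9, 3)])
        assert (c.centroid_x, c.centroid_y) == (7, 9)


class TestColocPixel:
    def test_rectangle_intersection(self):
        red = np.zeros((10, 10), bool)
        green = np.zeros((10, 10), bool)
        red[:, 0:6] = True
        green[:, 4:10] = True
        overlap, colocs = coloc_pixel(red, green)
        assert int(overlap.sum()) == 20
        assert len(colocs) == 1
        assert colocs[0].overlap_area == 20

    def test_identical_masks_idempotent(self, rng):
        mask = rng.random((20, 20)) < 0.2
        overlap, colocs = coloc_pixel(mask, mask)
        np.testing.assert_array_equal(overlap, mask)

    def test_three_channel_with_empty_blue(self):
        red = np.ones((5, 5), bool)
        green = np.ones((5, 5), bool)
        blue = np.zeros((5, 5), bool)
        overlap, colocs = coloc_pixel(red, green, blue)
        assert not overlap.any()
        assert colocs == []

    def test_overlap_bounded_by_channel_counts(self, rng):
        red = rng.random((30, 30)) < 0.4
        green = rng.random((30, 30)) < 0.4
        overlap, _ = coloc_pixel(red, green)
        assert int(overlap.sum()) <= min(int(red.sum()), int(green.sum()))

    def test_and_commutative_and_associative(self, rng):
        a = rng.random((15, 15)) < 0.5
        b = rng.random((15, 15)) < 0.5
        c = rng.random((15, 15)) < 0.5
        ab, _ = coloc_pixel(a, b, c)
        ba, _ = coloc_pixel(b, a, c)
        cb, _ = coloc_pixel(c, b, a)
        np.testing.assert_array_equal(ab, ba)
        np.testing.assert_array_equal(ab, cb)

    def test_min_size_filter(self):
        red = np.zeros((10, 10), bool)
        green = np.zeros((10, 10), bool)
        red[0, 0] = green[0, 0] = True           # 1-px overlap
        red[5:7, 5:7] = green[5:7, 5:7] = True   # 4-px overlap
        _, colocs = coloc_pixel(red, green, coloc_min_size=2)
        assert len(colocs) == 1
        assert colocs[0].overlap_area == 4

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            coloc_pixel(np.zeros((4, 4), bool), np.zeros((5, 5), bool))


class TestROI:
    def test_whole_image_identity(self, rng):
        mask = rng.random((12, 12)) < 0.5
        np.testing.assert_array_equal(apply_roi(mask, ROISpec()), mask)

    def test_circle_roi_clears_outside(self):
        mask = np.ones((41, 41), bool)
        roi = ROISpec(kind="circle", center_x=20, center_y=20, radius=10)
        out = apply_roi(mask, roi)
        rows, cols = np.ogrid[:41, :41]
        inside = (rows - 20) ** 2 + (cols - 20) ** 2 <= 100
        np.testing.assert_array_equal(out, inside)
        assert roi.area((41, 41)) == int(inside.sum())

    def test_all_false_mask_roi(self, tmp_path):
        import imageio.v3 as iio

        mask_path = tmp_path / "roi.png"
        iio.imwrite(mask_path, np.zeros((8, 8), np.uint8))
        roi = ROISpec(kind="mask", mask_path=str(mask_path))
        out = apply_roi(np.ones((8, 8), bool), roi)
        assert not out.any()

    def test_mask_roi_shape_mismatch(self, tmp_path):
        import imageio.v3 as iio

        mask_path = tmp_path / "roi.png"
        iio.imwrite(mask_path, np.zeros((4, 4), np.uint8))
        roi = ROISpec(kind="mask", mask_path=str(mask_path))
        with pytest.raises(ValueError, match="shape"):
            apply_roi(np.ones((8, 8), bool), roi)

    def test_parse_roundtrip(self):
        roi = ROISpec.from_string("circle:100,120,301")
        assert (roi.center_x, roi.center_y, roi.radius) == (100, 120, 301)
        assert ROISpec.from_string("whole").kind == "whole_image"
        with pytest.raises(ValueError):
            ROISpec.from_string("hexagon:1,2")


def test_modes_agree_on_disk_puncta():
    """Circular approximation and pixel overlap count the same synapses when
    puncta are ideal disks."""
    from puncta_coloc.puncta_detect import DetectionParams, detect_puncta

    shape = (128, 128)
    red = np.zeros(shape, bool)
    green = np.zeros(shape, bool)
    rows, cols = np.ogrid[:shape[0], :shape[1]]

    def paste(mask, cy, cx, r):
        mask |= (rows - cy) ** 2 + (cols - cx) ** 2 <= r * r

    # three overlapping pairs, one red-only, one green-only
    for cy, cx in [(20, 20), (60, 60), (100, 40)]:
        paste(red, cy, cx, 4)
        paste(green, cy, cx + 3, 4)
    paste(red, 20, 100, 4)
    paste(green, 110, 110, 4)

    params = DetectionParams(min_size=1)
    colocs_circ = coloc_circular(detect_puncta(red, params, "red"),
                                 detect_puncta(green, params, "green"))
    _, colocs_pix = coloc_pixel(red, green)
    assert len(colocs_circ) == len(colocs_pix) == 3
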