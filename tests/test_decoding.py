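import math

import numpy as np
import pytest

from kneeplan.decoding import (
    NotDetected,
    ONE_SIGMA_THRESHOLD,
    contour_subsection,
    decode_keypoint_argmax,
    decode_keypoint_fit,
    decode_line,
    mask_to_polygons,
)
from kneeplan.encoding import Heatmap, MultiLabelMask, encode_keypoint, encode_line, rasterize_mask
from kneeplan.geometry import Keypoint, PolygonRegion, Polyline
from kneeplan.metrics import line_moments


class TestArgmaxDecoding:
    def test_integer_round_trip(self):
        kp = Keypoint(120.0, 77.0, label="K1")
        out = decode_keypoint_argmax(encode_keypoint(kp, (256, 256)))
        assert (out.x, out.y) == (120.0, 77.0)
        assert out.confidence == pytest.approx(1.0)

    def test_all_zero_not_detected(self):
        out = decode_keypoint_argmax(Heatmap(grid=np.zeros((32, 32))))
        assert isinstance(out, NotDetected)

    def test_tie_break_lowest_y_then_x(self):
        grid = np.zeros((16, 16))
        grid[5, 9] = 0.8
        grid[5, 5] = 0.8
        grid[7, 2] = 0.8
        out = decode_keypoint_argmax(Heatmap(grid=grid))
        assert (out.x, out.y) == (5.0, 5.0)

    def test_floor_rule(self):
        grid = np.full((16, 16), 0.01)
        grid[3, 3] = 0.04
        assert isinstance(decode_keypoint_argmax(Heatmap(grid=grid)), NotDetected)


class TestGaussianFitDecoding:
    def test_subpixel_recovery(self):
        kp = Keypoint(120.4, 77.6, label="K1")
        hm = encode_keypoint(kp, (256, 256))
        out = decode_keypoint_fit(hm)
        assert out.x == pytest.approx(120.4, abs=0.05)
        assert out.y == pytest.approx(77.6, abs=0.05)

    def test_fit_beats_argmax_on_subpixel_truth(self):
        kp = Keypoint(60.45, 30.52, label="K1")
        hm = encode_keypoint(kp, (128, 128))
        am = decode_keypoint_argmax(hm)
        fit = decode_keypoint_fit(hm)
        err_am = math.hypot(am.x - kp.x, am.y - kp.y)
        err_fit = math.hypot(fit.x - kp.x, fit.y - kp.y)
        assert err_fit < err_am
        assert err_am <= math.hypot(0.5, 0.5) + 1e-9

    def test_flat_input_not_detected(self):
        assert isinstance(decode_keypoint_fit(Heatmap(grid=np.zeros((32, 32)))), NotDetected)


class TestLineDecoding:
    @pytest.mark.parametrize("angle", [0.0, 30.0, 60.0, 90.0, -45.0])
    def test_angle_round_trip(self, angle):
        c = np.array([64.0, 64.0])
        d = np.array([math.cos(math.radians(angle)), math.sin(math.radians(angle))])
        line = Polyline(points=np.vstack([c - 40 * d, c + 40 * d]), label="L1")
        hm = encode_line(line, (128, 128), sigma=4.0)
        decoded = decode_line(hm)
        assert isinstance(decoded, Polyline)
        re_encoded = encode_line(decoded, (128, 128), sigma=4.0)
        result = line_moments(re_encoded)
        assert not isinstance(result, NotDetected)
        _, gamma = result
        target = angle if -90 < angle <= 90 else angle - 180 * np.sign(angle)
        diff = abs(gamma - target)
        assert min(diff, 180 - diff) < 0.5

    def test_vertical_line_no_singularity(self):
        line = Polyline(points=np.array([[64.0, 20.0], [64.0, 110.0]]), label="L1")
        decoded = decode_line(encode_line(line, (128, 128), sigma=4.0))
        assert isinstance(decoded, Polyline)
        assert np.ptp(decoded.points[:, 0]) < 2.0  # stays essentially vertical

    def test_all_zero_not_detected(self):
        assert isinstance(decode_line(Heatmap(grid=np.zeros((64, 64)))), NotDetected)

    def test_invariance_to_positive_rescaling(self):
        line = Polyline(points=np.array([[20.0, 30.0], [100.0, 90.0]]), label="L1")
        hm = encode_line(line, (128, 128), sigma=4.0)
        a = decode_line(hm)
        # rescale values above threshold but keep the same selected point set
        grid = np.where(hm.grid >= ONE_SIGMA_THRESHOLD, hm.grid * 0.999 + 0.001, hm.grid)
        b = decode_line(Heatmap(grid=grid, sigma=4.0))
        assert np.max(np.abs(a.points - b.points)) < 1.0


class TestMaskToPolygons:
    def test_filled_square_area(self):
        grid = np.zeros((64, 64), dtype=np.uint8)
        grid[10:30, 15:35] = 1
        res = mask_to_polygons(MultiLabelMask(labels=("S1",), data=grid[None]))[0]
        assert not isinstance(res.region, NotDetected)
        assert not res.fragmented
        assert res.region.area == pytest.approx(400, rel=0.02)

    def test_small_fragment_dropped(self):
        grid = np.zeros((64, 64), dtype=np.uint8)
        grid[5:45, 5:30] = 1  # area 1000
        grid[50:51, 50:55] = 1  # area 5
        res = mask_to_polygons(MultiLabelMask(labels=("S1",), data=grid[None]))[0]
        assert not res.fragmented
        assert res.region.area == pytest.approx(1000, rel=0.02)

    def test_fragmentation_flagged(self):
        grid = np.zeros((80, 80), dtype=np.uint8)
        grid[5:45, 5:30] = 1  # 1000
        grid[50:70, 40:70] = 1  # 600
        res = mask_to_polygons(MultiLabelMask(labels=("S1",), data=grid[None]))[0]
        assert res.fragmented
        assert res.region.area == pytest.approx(1000, rel=0.02)

    def test_empty_channel_not_detected(self):
        res = mask_to_polygons(MultiLabelMask(labels=("S1",), data=np.zeros((1, 32, 32), np.uint8)))[0]
        assert isinstance(res.region, NotDetected)

    def test_round_trip_convex_area(self, rng):
        from scipy.spatial import ConvexHull

        pts = rng.uniform(30, 220, size=(15, 2))
        hull = pts[ConvexHull(pts).vertices]
        region = PolygonRegion(shell=hull, label="S1")
        mask = rasterize_mask([region], (256, 256))
        res = mask_to_polygons(mask)[0]
        assert res.region.area == pytest.approx(region.area, rel=0.02)


class TestContourSubsection:
    def _square(self):
        return PolygonRegion(
            shell=np.array([[10.0, 10.0], [50.0, 10.0], [50.0, 50.0], [10.0, 50.0]]), label="S1"
        )

    def test_uniform_weight_returns_whole_contour(self):
        hm = Heatmap(grid=np.ones((64, 64)))
        out = contour_subsection(self._square(), hm)
        assert isinstance(out, Polyline)
        assert out.length() == pytest.approx(160.0, rel=0.02)

    def test_half_plane_weight(self):
        grid = np.zeros((64, 64))
        grid[:, :30] = 1.0
        out = contour_subsection(self._square(), Heatmap(grid=grid))
        assert isinstance(out, Polyline)
        assert np.all(out.points[:, 0] <= 30.5)

    def test_zero_weight_not_detected(self):
        out = contour_subsection(self._square(), Heatmap(grid=np.zeros((64, 64))))
        assert isinstance(out, NotDetected)
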