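"""Image pipeline: background, contours, the four morphometric features."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.special import ellipe

from acoustosort.features import (
    Contour,
    FeatureConfig,
    area_ratio,
    brightness,
    deformation,
    detect_contour,
    estimate_background,
    extract_events,
)
from acoustosort.synthetic import EllipseObject, render_frames

BG = 50.0


def _flat_bg(shape=(128, 128)):
    return np.full(shape, BG)


class TestBackground:
    def test_identical_frames_recovered_exactly(self):
        frame = np.arange(100, dtype=float).reshape(10, 10)
        stack = np.stack([frame] * 5)
        np.testing.assert_array_equal(estimate_background(stack), frame)

    def test_noisy_empty_channel(self):
        rng = np.random.default_rng(0)
        stack = np.clip(rng.normal(BG, 2.0, size=(100, 32, 32)), 0, 255)
        bg = estimate_background(stack)
        assert np.abs(bg - BG).max() < 1.0

    def test_median_robust_to_one_cell_frame(self):
        obj = [[EllipseObject(center=(16, 16), a=8, b=8, intensity=120.0)]]
        cell = render_frames(obj, shape=(32, 32), background_level=BG).frames[0]
        stack = np.stack([np.full((32, 32), BG)] * 99 + [cell.astype(float)])
        bg = estimate_background(stack)
        np.testing.assert_allclose(bg, BG)

    def test_single_frame_instructs_explicit_background(self):
        with pytest.raises(ValueError, match="explicit background"):
            estimate_background(np.zeros((1, 8, 8)))


class TestDetectContour:
    def test_blank_frame(self):
        assert detect_contour(_flat_bg(), _flat_bg()) == []

    def test_disk_area_within_two_percent(self):
        obj = [[EllipseObject(center=(64, 64), a=20, b=20, intensity=100.0)]]
        stack = render_frames(obj, background_level=BG)
        dets = detect_contour(stack.frames[0], _flat_bg(), threshold=10)
        assert len(dets) == 1
        assert dets[0].raw.area == pytest.approx(math.pi * 400, rel=0.02)

    def test_two_disks_ordered_by_area(self):
        objs = [[
            EllipseObject(center=(30, 30), a=8, b=8, intensity=100.0),
            EllipseObject(center=(90, 90), a=15, b=15, intensity=100.0),
        ]]
        stack = render_frames(objs, background_level=BG)
        dets = detect_contour(stack.frames[0], _flat_bg())
        assert len(dets) == 2
        assert dets[0].raw.area > dets[1].raw.area

    def test_min_area_filter(self):
        obj = [[EllipseObject(center=(64, 64), a=3, b=3, intensity=100.0)]]
        stack = render_frames(obj, background_level=BG)
        assert detect_contour(stack.frames[0], _flat_bg(), min_area_px=100) == []

    def test_dark_objects_detected_via_absolute_difference(self):
        obj = [[EllipseObject(center=(64, 64), a=12, b=12, intensity=5.0)]]
        stack = render_frames(obj, background_level=BG)
        dets = detect_contour(stack.frames[0], _flat_bg())
        assert len(dets) == 1

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            detect_contour(np.zeros((4, 4)), np.zeros((5, 5)))


class TestDeformation:
    def test_circle_is_zero(self):
        r = 7.3
        assert deformation(math.pi * r**2, 2 * math.pi * r) == pytest.approx(0.0,
                                                                             abs=1e-12)

    def test_ellipse_10_by_5_against_arc_length_oracle(self):
        # independent oracle: high-resolution polygonal arc length
        t = np.linspace(0, 2 * np.pi, 200_001)
        x, y = 10 * np.cos(t), 5 * np.sin(t)
        perimeter = np.hypot(np.diff(x), np.diff(y)).sum()
        d = deformation(50 * math.pi, perimeter)
        assert d == pytest.approx(0.083, abs=0.001)
        # cross-check the oracle itself against the elliptic integral
        assert perimeter == pytest.approx(4 * 10 * ellipe(1 - 0.25), rel=1e-9)

    def test_sub_circular_perimeter_gives_negative(self):
        area = 100.0
        l_circle = 2 * math.sqrt(math.pi * area)
        assert deformation(area, l_circle - 1e-6) < 0

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            deformation(0.0, 10.0)
        with pytest.raises(ValueError):
            deformation(10.0, 0.0)

    @given(area=st.floats(1.0, 1e4), perimeter=st.floats(1.0, 1e4),
           scale=st.floats(0.1, 10.0))
    def test_scale_invariance(self, area, perimeter, scale):
        d0 = deformation(area, perimeter)
        d1 = deformation(area * scale**2, perimeter * scale)
        assert d1 == pytest.approx(d0, abs=1e-9)


class TestAreaRatio:
    def test_convex_polygon_is_one(self):
        square = Contour(np.array([[0, 0], [0, 10], [10, 10], [10, 0]], float))
        assert area_ratio(square.convex_hull(), square) == pytest.approx(1.0)

    def test_dented_square_analytic(self):
        # push the bottom-edge midpoint inward: removes triangle of area 20
        raw = Contour(np.array([[0, 0], [4, 5], [0, 10], [10, 10], [10, 0]], float))
        hull = raw.convex_hull()
        assert hull.area == pytest.approx(100.0)
        assert raw.area == pytest.approx(80.0)
        assert area_ratio(hull, raw) == pytest.approx(100.0 / 80.0)

    def test_concavity_removing_20_percent_gives_1_25(self):
        # crescent-like: concavity removes exactly 20 % of the hull area
        raw = Contour(np.array([[0, 0], [4, 5], [0, 10], [10, 10], [10, 0]], float))
        assert area_ratio(raw.convex_hull(), raw) == pytest.approx(1.25)

    def test_zero_area_raw(self):
        degenerate = Contour(np.array([[0, 0], [1, 1], [2, 2]], float))
        with pytest.raises(ValueError):
            area_ratio(degenerate, degenerate)


class TestBrightness:
    def test_uniform_frame(self):
        frame = np.full((32, 32), 100.0)
        contour = Contour(np.array([[5, 5], [5, 25], [25, 25], [25, 5]], float))
        assert brightness(frame, contour) == pytest.approx(100.0)

    def test_disk_mean_intensity(self):
        obj = [[EllipseObject(center=(64, 64), a=20, b=20, intensity=120.0)]]
        # hard-edged render so every interior pixel is exactly 120
        stack = render_frames(obj, background_level=BG, supersample=1)
        det = detect_contour(stack.frames[0], _flat_bg())[0]
        assert brightness(stack.frames[0], det.raw) == pytest.approx(120.0, abs=1.0)

    def test_half_and_half_disk(self):
        # contour taken on the uniform disk, intensity then split 120/60
        obj = [[EllipseObject(center=(64, 64), a=20, b=20, intensity=120.0)]]
        stack = render_frames(obj, background_level=BG, supersample=1)
        det = detect_contour(stack.frames[0], _flat_bg())[0]
        frame = stack.frames[0].astype(float)
        frame[:, 64:] = np.where(frame[:, 64:] > BG, 60.0, BG)
        assert brightness(frame, det.raw) == pytest.approx(90.0, abs=1.0)

    def test_bounded_by_pixel_range(self):
        rng = np.random.default_rng(1)
        obj = [[EllipseObject(center=(64, 64), a=15, b=10, intensity=110.0)]]
        stack = render_frames(obj, background_level=BG, noise_sd=2.0, seed=5)
        det = detect_contour(stack.frames[0], _flat_bg())[0]
        b = brightness(stack.frames[0], det.raw)
        assert stack.frames[0].min() <= b <= stack.frames[0].max()


class TestExtractEvents:
    def test_empty_stack(self):
        ev = extract_events(np.zeros((0, 16, 16)))
        assert len(ev) == 0

    def test_recovery_of_known_ellipses(self):
        rng = np.random.default_rng(21)
        objs, gt_area, gt_d = [], [], []
        for _ in range(40):
            a = rng.uniform(8, 24)
            b = a / rng.uniform(1.0, 2.5)
            obj = EllipseObject(center=(64, 64), a=a, b=b,
                                theta=rng.uniform(0, np.pi), intensity=110.0)
            objs.append([obj])
        stack = render_frames(objs, noise_sd=1.0, seed=22, background_level=BG)
        cfg = FeatureConfig(track_max_frame_gap=0)
        ev = extract_events(stack, cfg, background=_flat_bg())
        assert len(ev) == 40
        gt_area = np.array([f[0]["area_px2"] for f in stack.ground_truth]) * 0.34**2
        gt_d = np.array([f[0]["deformation"] for f in stack.ground_truth])
        area_err = np.abs(ev["area_um2"].to_numpy() - gt_area) / gt_area
        d_err = np.abs(ev["deformation"].to_numpy() - gt_d)
        assert area_err.mean() < 0.02
        assert d_err.mean() < 0.01
        assert (ev["area_ratio"] >= 1).all()

    def test_track_deduplication_single_event(self):
        # one cell drifting 4 px/frame across 5 frames -> one event
        objs = [[EllipseObject(center=(40, 30 + 4 * i), a=10, b=8, intensity=110.0)]
                for i in range(5)]
        stack = render_frames(objs, shape=(80, 160), background_level=BG)
        ev = extract_events(stack, FeatureConfig(track_max_move_px=8.0),
                            background=np.full((80, 160), BG))
        assert len(ev) == 1
        assert ev["n_frames"].iloc[0] == 5

    def test_dedup_disabled_keeps_every_detection(self):
        objs = [[EllipseObject(center=(40, 30 + 4 * i), a=10, b=8, intensity=110.0)]
                for i in range(5)]
        stack = render_frames(objs, shape=(80, 160), background_level=BG)
        ev = extract_events(stack, FeatureConfig(track_max_frame_gap=0),
                            background=np.full((80, 160), BG))
        assert len(ev) == 5

    def test_times_follow_frame_rate(self):
        objs = [[EllipseObject(center=(32, 32), a=8, b=8, intensity=110.0)], []]
        stack = render_frames(objs, shape=(64, 64), background_level=BG,
                              frame_rate=2700.0)
        ev = extract_events(stack, background=np.full((64, 64), BG))
        assert ev["time_s"].iloc[0] == pytest.approx(0.0)
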