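"""Landmark-to-axes geometry: overlays, trajectories, depths, angles."""

import math

import numpy as np
import pytest

from ecobode import (
    CochlearLandmarks,
    Point2D,
    SpiralModel,
    apical_insertion_depth,
    electrode_aids,
    electrode_depths,
    fit_trajectory,
    monitoring_axis,
    overlay_slices,
    point_angles,
)
from ecobode.errors import GeometryError, InputError
from ecobode.geometry import ElectrodeGeometry


def _line_landmarks(length=10.0, n=5, scale=1.0):
    xs = np.linspace(0.0, length, n)
    return CochlearLandmarks(
        center=Point2D(0.0, 5.0),
        round_window=Point2D(xs[0], 0.0),
        array_points=tuple(Point2D(x, 0.0) for x in xs[1:]),
        scale_mm_per_px=scale,
    )


def _circle_landmarks(R=3.0, span=2 * math.pi, n_knots=12):
    thetas = np.linspace(0.0, span, n_knots)
    pts = [Point2D(R * math.cos(t), R * math.sin(t)) for t in thetas]
    return CochlearLandmarks(
        center=Point2D(0.0, 0.0),
        round_window=pts[0],
        array_points=tuple(pts[1:]),
    )


class TestOverlay:
    def test_single_image_is_identity(self):
        im = np.arange(12, dtype=np.uint8).reshape(3, 4)
        assert np.array_equal(overlay_slices([im]), im)

    def test_disjoint_bright_pixels_both_survive(self):
        a = np.zeros((4, 4), dtype=np.uint8)
        b = np.zeros((4, 4), dtype=np.uint8)
        a[1, 1] = 200
        b[2, 3] = 150
        out = overlay_slices([a, b])
        assert out[1, 1] == 200 and out[2, 3] == 150

    def test_matches_elementwise_maximum_oracle(self, rng):
        a = rng.integers(0, 256, (16, 16)).astype(np.uint8)
        b = rng.integers(0, 256, (16, 16)).astype(np.uint8)
        out = overlay_slices([a, b])
        for i in range(16):  # brute-force pixel loop
            for j in range(16):
                assert out[i, j] == max(a[i, j], b[i, j])

    def test_shape_mismatch_and_empty_rejected(self):
        with pytest.raises(InputError):
            overlay_slices([np.zeros((2, 2)), np.zeros((3, 3))])
        with pytest.raises(InputError):
            overlay_slices([])


class TestTrajectory:
    def test_collinear_knots_give_straight_arc_length(self):
        traj = fit_trajectory(_line_landmarks(length=10.0), n_samples=10_000)
        assert traj.total_length == pytest.approx(10.0, abs=1e-3)

    @pytest.mark.parametrize("span,n_knots", [(1.5 * math.pi, 8), (2 * math.pi, 12)])
    def test_circle_arc_length_closed_form(self, span, n_knots):
        R = 3.0
        traj = fit_trajectory(_circle_landmarks(R, span, n_knots), n_samples=10**6)
        assert traj.total_length == pytest.approx(R * span, rel=1e-3)

    def test_chordal_arc_length_converges_from_below(self):
        lm = _circle_landmarks(3.0, math.pi, 9)
        lengths = [fit_trajectory(lm, n_samples=n).total_length
                   for n in (100, 1000, 10_000, 100_000)]
        assert all(a < b for a, b in zip(lengths, lengths[1:]))

    def test_pixel_calibration_scales_arc_length(self):
        mm = fit_trajectory(_line_landmarks(10.0, scale=1.0), 5000).total_length
        px = fit_trajectory(_line_landmarks(10.0, scale=0.5), 5000).total_length
        assert px == pytest.approx(mm / 2, rel=1e-9)

    def test_duplicate_consecutive_knots_rejected(self):
        with pytest.raises(GeometryError):
            CochlearLandmarks(
                center=Point2D(0, 5),
                round_window=Point2D(0, 0),
                array_points=(Point2D(1, 0), Point2D(1, 0), Point2D(2, 0)),
            )

    def test_too_few_samples_rejected(self):
        with pytest.raises(InputError):
            fit_trajectory(_line_landmarks(), n_samples=10)


class TestApicalDepth:
    def test_straight_path_end_depth(self):
        lm = _line_landmarks(length=20.0)
        traj = fit_trajectory(lm, n_samples=100_000)
        d = apical_insertion_depth(traj, lm.array_points[-1])
        assert d == pytest.approx(20.0, abs=1e-3)

    def test_round_window_depth_is_zero(self):
        lm = _line_landmarks(length=20.0)
        traj = fit_trajectory(lm, n_samples=100_000)
        assert apical_insertion_depth(traj, lm.round_window) == pytest.approx(0.0, abs=1e-3)

    def test_archimedean_spiral_analytic_depth(self, spiral_fixture, midscala):
        _, landmarks, truth = spiral_fixture
        traj = fit_trajectory(landmarks.to_mm(), n_samples=10**6)
        d = apical_insertion_depth(traj, landmarks.to_mm().array_points[-1])
        assert d == pytest.approx(truth.insertion_depth_mm[0], rel=5e-3)

    def test_inconsistent_apical_point_rejected(self):
        traj = fit_trajectory(_line_landmarks(), n_samples=10_000)
        with pytest.raises(GeometryError):
            apical_insertion_depth(traj, Point2D(5.0, 3.0))


class _Spec:
    def __init__(self, n, length):
        self.n_contacts = n
        self.array_length_mm = length


class TestElectrodeDepths:
    def test_arithmetic_sequence_without_correction(self):
        d = electrode_depths(20.0, _Spec(16, 15.0))
        assert d[0] == 20.0 and d[-1] == pytest.approx(5.0)
        assert np.allclose(np.diff(d), -1.0)

    def test_negative_basal_depth_triggers_correction(self):
        # shallow insertion: basal contact would land at negative depth
        d = electrode_depths(14.0, _Spec(16, 15.0))
        assert d[0] == 15.0  # apical reset to the array length
        assert d[-1] == 0.0  # basal reset to the round window
        assert np.allclose(np.diff(d), -1.0)

    def test_two_contacts(self):
        d = electrode_depths(18.0, _Spec(2, 15.0))
        assert list(d) == [18.0, 3.0]

    def test_nonpositive_apical_depth_rejected(self):
        with pytest.raises(InputError):
            electrode_depths(0.0, _Spec(16, 15.0))


class TestPointAngles:
    @staticmethod
    def _landmarks_at(angles_deg, center=(0.0, 0.0), R=2.0, sense=1.0, rot=0.0):
        cx, cy = center
        rw = Point2D(cx + R * math.cos(rot), cy + R * math.sin(rot))
        r_arr = 0.9 * R  # array sits inside the RW radius, avoids coincident knots
        pts = tuple(
            Point2D(
                cx + r_arr * math.cos(rot + sense * math.radians(a)),
                cy + r_arr * math.sin(rot + sense * math.radians(a)),
            )
            for a in angles_deg
        )
        return CochlearLandmarks(center=Point2D(cx, cy), round_window=rw, array_points=pts)

    def test_basal_knot_on_rw_ray_is_zero(self):
        lm = self._landmarks_at([0.0, 40.0])
        assert point_angles(lm)[0] == pytest.approx(0.0, abs=1e-9)

    def test_quarter_turn_knot_is_ninety(self):
        lm = self._landmarks_at([30.0, 90.0])
        assert point_angles(lm)[1] == pytest.approx(90.0, abs=1e-9)

    def test_unwrapping_beyond_full_turn(self, spiral_fixture):
        _, landmarks, truth = spiral_fixture
        ang = point_angles(landmarks)
        assert ang[-1] == pytest.approx(truth.insertion_angle_deg[0], abs=2.0)
        assert ang[-1] > 360.0

    @pytest.mark.parametrize("rot,shift,sense", [
        (0.0, (0.0, 0.0), 1.0),
        (1.1, (3.0, -2.0), 1.0),
        (0.0, (0.0, 0.0), -1.0),   # mirror image (other ear / y-down raster)
        (2.7, (-5.0, 4.0), -1.0),
    ])
    def test_invariant_under_rotation_translation_mirror(self, rot, shift, sense):
        angles = [20.0, 100.0, 200.0, 300.0, 380.0]
        base = point_angles(self._landmarks_at(angles))
        moved = point_angles(
            self._landmarks_at(angles, center=shift, sense=sense, rot=rot)
        )
        assert np.allclose(base, moved, atol=1e-9)

    def test_monotone_nondecreasing(self, spiral_fixture):
        _, landmarks, _ = spiral_fixture
        ang = point_angles(landmarks)
        assert np.all(np.diff(ang) >= 0)

    def test_knot_at_center_rejected(self):
        lm = CochlearLandmarks(
            center=Point2D(0, 0),
            round_window=Point2D(2, 0),
            array_points=(Point2D(1, 1), Point2D(0, 0)),
        )
        with pytest.raises(GeometryError):
            point_angles(lm)


class TestElectrodeAids:
    def test_four_contacts_example(self):
        assert list(electrode_aids(10.0, 370.0, 4)) == [370.0, 250.0, 130.0, 10.0]

    def test_degenerate_equal_angles(self):
        assert np.allclose(electrode_aids(45.0, 45.0, 7), 45.0)

    def test_matches_linspace_oracle(self):
        got = electrode_aids(0.0, 400.0, 21)
        expected = [400.0 - 20.0 * i for i in range(21)]  # brute force grid
        assert np.allclose(got, expected)

    def test_ordering_violation_rejected(self):
        with pytest.raises(InputError):
            electrode_aids(370.0, 10.0, 4)


class TestMonitoringAxis:
    @pytest.fixture()
    def geometry(self):
        n = 16
        depths = np.linspace(16.0, 1.0, n)
        angles = np.linspace(520.0, 40.0, n)
        return ElectrodeGeometry(insertion_depth_mm=depths, insertion_angle_deg=angles)

    @staticmethod
    def _markers(geometry, speed=0.5):
        d = geometry.insertion_depth_mm
        return [(float((d[0] - dj) / speed), j + 1) for j, dj in enumerate(d)]

    def test_apical_marker_depth_is_zero(self, geometry):
        markers = self._markers(geometry)
        depth, _ = monitoring_axis(geometry, markers, [markers[0][0]])
        assert depth[0] == 0.0

    def test_final_marker_depth_is_contact_span(self, geometry):
        markers = self._markers(geometry)
        depth, _ = monitoring_axis(geometry, markers, [markers[-1][0]])
        d = geometry.insertion_depth_mm
        assert depth[0] == pytest.approx(d[0] - d[-1])

    def test_uniform_speed_recovers_tip_line(self, geometry):
        speed = 0.5
        markers = self._markers(geometry, speed)
        times = np.array([t for t, _ in markers])
        depth, _ = monitoring_axis(geometry, markers, times)
        assert np.allclose(depth, speed * times, atol=1e-6)

    def test_marker_identity_depth_plus_contact_depth(self, geometry):
        markers = self._markers(geometry)
        d = geometry.insertion_depth_mm
        depth, _ = monitoring_axis(geometry, markers, [t for t, _ in markers])
        assert np.allclose(depth + d, d[0])

    def test_extrapolation_before_first_marker_clamped_at_zero(self, geometry):
        markers = self._markers(geometry)[5:]  # first marker no longer at t=0
        with pytest.warns(UserWarning):
            depth, aid = monitoring_axis(geometry, markers, [-100.0])
        assert depth[0] == 0.0 and aid[0] >= 0.0

    def test_aids_follow_depth_angle_map(self, geometry):
        markers = self._markers(geometry)
        d = geometry.insertion_depth_mm
        a = geometry.insertion_angle_deg
        depth, aid = monitoring_axis(geometry, markers, [t for t, _ in markers])
        # the sweep axes' depth<->angle line, extended to depth 0, clamped at 0 deg
        slope = (a[0] - a[-1]) / (d[0] - d[-1])
        expected = np.clip(a[-1] + slope * (depth - d[-1]), 0.0, None)
        assert np.allclose(aid, expected, atol=1e-9)
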