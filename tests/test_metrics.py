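"""Reference frame, perpendicular/parallel constructions and cohort stats."""

from __future__ import annotations

import numpy as np
import pytest

from quadzone import (
    ZoneLandmarks,
    aggregate_cohort,
    fit_reference_frame,
    foot_of_perpendicular,
    line_parallel_intersection,
    measure_record,
)
from quadzone.errors import CohortError, FrameError, NoIntersectionError
from quadzone.metrics import MEASUREMENTS, MeasurementRecord
from quadzone import _geometry as geom


def grid_points(z=0.0, n=15, half=30.0):
    xs = np.linspace(-half, half, n)
    X, Y = np.meshgrid(xs, xs, indexing="ij")
    return np.stack([X.ravel(), Y.ravel(), np.full(X.size, z)], axis=-1)


STRAIGHT_BRIM = np.array([[-40.0, 0.0, 0.0], [40.0, 0.0, 0.0]])


class TestReferenceFrame:
    def test_plane_points_give_z_normal(self):
        frame = fit_reference_frame(grid_points(), STRAIGHT_BRIM)
        assert abs(frame.normal @ [0, 0, 1]) == pytest.approx(1.0, abs=1e-12)
        assert abs(frame.brim_tangent @ [1, 0, 0]) == pytest.approx(1.0, abs=1e-12)

    def test_noisy_plane_normal_within_one_degree(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            pts = grid_points()
            pts[:, 2] += rng.normal(0, 0.1, len(pts))
            frame = fit_reference_frame(pts, STRAIGHT_BRIM)
            angle = np.degrees(np.arccos(min(abs(frame.normal @ [0, 0, 1]), 1.0)))
            assert angle < 1.0

    def test_degenerate_input_raises(self):
        with pytest.raises(FrameError):
            fit_reference_frame(np.array([[0, 0, 0], [1, 0, 0]]), STRAIGHT_BRIM)
        collinear = np.stack([np.linspace(0, 1, 10), np.zeros(10), np.zeros(10)], axis=-1)
        with pytest.raises(FrameError):
            fit_reference_frame(collinear, STRAIGHT_BRIM)


class TestFootOfPerpendicular:
    def test_orthogonal_projection_on_straight_brim(self):
        frame = fit_reference_frame(grid_points(), STRAIGHT_BRIM)
        foot = foot_of_perpendicular([5.0, 3.0, 0.0], STRAIGHT_BRIM, frame)
        np.testing.assert_allclose(foot, [5.0, 0.0, 0.0], atol=1e-9)

    def test_point_beyond_range_falls_back_to_nearest_endpoint(self):
        frame = fit_reference_frame(grid_points(), STRAIGHT_BRIM)
        foot = foot_of_perpendicular([55.0, 3.0, 0.0], STRAIGHT_BRIM, frame)
        np.testing.assert_allclose(foot, [40.0, 0.0, 0.0], atol=1e-9)

    def test_circular_arc_matches_bruteforce_minimisation(self):
        # Arc of radius 50 about (0,-50): the perpendicular foot is the
        # radial projection; check against brute force over dense samples.
        theta = np.linspace(-0.6, 0.6, 241)
        arc = np.stack([50 * np.sin(theta), -50 + 50 * np.cos(theta), np.zeros_like(theta)], -1)
        frame = fit_reference_frame(grid_points(), arc)
        p = np.array([10.0, -10.0, 0.0])
        foot = foot_of_perpendicular(p, arc, frame)
        dense = geom.densify_polyline(arc, 0.05)
        brute = dense[np.argmin(np.linalg.norm(dense - p, axis=1))]
        assert np.linalg.norm(foot - brute) < 0.06


class TestParallelIntersection:
    def _frame(self):
        return fit_reference_frame(grid_points(), STRAIGHT_BRIM)

    def _circle(self, cx, cy, r, n=720):
        t = np.linspace(0, 2 * np.pi, n)
        return np.stack([cx + r * np.cos(t), cy + r * np.sin(t), np.zeros_like(t)], -1)

    def test_line_circle_solution(self):
        frame = self._frame()
        hit = line_parallel_intersection([0.0, 10.0, 0.0], np.array([1.0, 0.0]),
                                         self._circle(20, 10, 5), frame)
        np.testing.assert_allclose(hit, [15.0, 10.0, 0.0], atol=1e-3)

    def test_point_on_polyline_returns_itself(self):
        frame = self._frame()
        hit = line_parallel_intersection([15.0, 10.0, 0.0], np.array([1.0, 0.0]),
                                         self._circle(20, 10, 5), frame)
        np.testing.assert_allclose(hit, [15.0, 10.0, 0.0], atol=1e-3)

    def test_missing_target_raises(self):
        frame = self._frame()
        with pytest.raises(NoIntersectionError):
            line_parallel_intersection([0.0, 30.0, 0.0], np.array([1.0, 0.0]),
                                       self._circle(20, 10, 5), frame)


def _closed_form_setup():
    """Hand-placed landmarks over a straight brim and circular foramen with
    every distance known in closed form (coordinates in mm, z = 0 plane)."""
    brim = STRAIGHT_BRIM
    t = np.linspace(0, 2 * np.pi, 1440)
    foramen = np.stack([10 + 6 * np.cos(t), -20 + 6 * np.sin(t), np.zeros_like(t)], -1)
    foramen_top = np.array([10.0, -14.0, 0.0])
    lmk = ZoneLandmarks(
        E=np.array([-8.0, 0.0, 0.0]),
        F=np.array([-2.0, 0.0, 0.0]),
        G=np.array([0.0, -18.0, 0.0]),
        H=np.array([5.0, -21.0, 0.0]),
    )
    # K = (10, 0); M = (0, 0); P = (5, 0)
    # N: horizontal line y = -18 meets the circle at x = 10 +- sqrt(36 - 4)
    # Q: y = -21 meets it at x = 10 +- sqrt(36 - 1)
    expected = {
        "EK": 18.0 / 10, "FK": 12.0 / 10, "GM": 18.0 / 10,
        "GN": (10 - np.sqrt(32)) / 10, "HP": 21.0 / 10, "HQ": (5 - (10 - np.sqrt(35))) / 10,
    }
    return brim, foramen, foramen_top, lmk, expected


class TestMeasureRecord:
    def test_closed_form_coordinates(self):
        brim, foramen, top, lmk, expected = _closed_form_setup()
        frame = fit_reference_frame(grid_points(), brim)
        rec = measure_record(lmk, brim, foramen, top, frame, "s", 2.95)
        for name, val in expected.items():
            assert getattr(rec, name) == pytest.approx(val, abs=2e-4), name

    def test_degenerate_zero_distances(self):
        # A foramen circle reaching up to the brim keeps the brim-parallel
        # lines through landmarks on or near the brim intersectable.
        brim = STRAIGHT_BRIM
        t = np.linspace(0, 2 * np.pi, 1440)
        foramen = np.stack([10 + 6 * np.cos(t), -2 + 6 * np.sin(t), np.zeros_like(t)], -1)
        top = np.array([10.0, 4.0, 0.0])
        frame = fit_reference_frame(grid_points(), brim)
        # K = foot of (10, 4) on y = 0 is (10, 0); E placed there -> EK = 0.
        lmk = ZoneLandmarks(E=np.array([10.0, 0.0, 0.0]), F=np.array([-2.0, 0.0, 0.0]),
                            G=np.array([3.0, 0.0, 0.0]), H=np.array([5.0, -4.0, 0.0]))
        rec = measure_record(lmk, brim, foramen, top, frame)
        assert rec.EK == pytest.approx(0.0, abs=1e-9)
        # G on the brim: its perpendicular foot is itself -> GM = 0.
        assert rec.GM == pytest.approx(0.0, abs=1e-9)

    def test_rigid_motion_invariance(self):
        brim, foramen, top, lmk, _ = _closed_form_setup()
        region = grid_points()
        frame = fit_reference_frame(region, brim)
        base = measure_record(lmk, brim, foramen, top, frame)

        rng = np.random.default_rng(17)
        A = rng.normal(size=(3, 3))
        Q, _ = np.linalg.qr(A)
        if np.linalg.det(Q) < 0:
            Q[:, 0] *= -1
        shift = rng.uniform(-40, 40, 3)
        xf = lambda p: np.asarray(p) @ Q.T + shift  # noqa: E731
        frame2 = fit_reference_frame(xf(region), xf(brim))
        lmk2 = ZoneLandmarks(E=xf(lmk.E), F=xf(lmk.F), G=xf(lmk.G), H=xf(lmk.H))
        moved = measure_record(lmk2, xf(brim), xf(foramen), xf(top), frame2)
        for m in MEASUREMENTS:
            assert getattr(moved, m) == pytest.approx(getattr(base, m), abs=1e-9)

    def test_uniform_scaling_scales_measurements(self):
        brim, foramen, top, lmk, _ = _closed_form_setup()
        region = grid_points()
        frame = fit_reference_frame(region, brim)
        base = measure_record(lmk, brim, foramen, top, frame)
        s = 1.37
        frame2 = fit_reference_frame(region * s, brim * s)
        lmk2 = ZoneLandmarks(E=lmk.E * s, F=lmk.F * s, G=lmk.G * s, H=lmk.H * s)
        scaled = measure_record(lmk2, brim * s, foramen * s, top * s, frame2)
        for m in MEASUREMENTS:
            assert getattr(scaled, m) == pytest.approx(s * getattr(base, m), rel=1e-9)


class TestAggregateCohort:
    def _rec(self, val, offset=2.95, sid="s"):
        return MeasurementRecord(sid, offset, *(val,) * 6)

    def test_mean_min_max_formatting(self):
        recs = [self._rec(v) for v in (2.58, 2.90, 3.22)]
        summary = aggregate_cohort(recs)
        cell = summary.formatted().loc["2.95 mm", "EK"]
        assert cell == "2.90 (2.58–3.22)"
        assert summary.n[2.95] == 3

    def test_single_record(self):
        summary = aggregate_cohort([self._rec(1.74)])
        assert summary.formatted().loc["2.95 mm", "FK"] == "1.74 (1.74–1.74)"

    def test_min_le_mean_le_max_invariant(self):
        rng = np.random.default_rng(2)
        recs = [self._rec(v, offset=d) for d in (2.95, 6.0) for v in rng.uniform(1, 4, 9)]
        t = aggregate_cohort(recs).table
        for m in MEASUREMENTS:
            assert (t[(m, "min")] <= t[(m, "mean")]).all()
            assert (t[(m, "mean")] <= t[(m, "max")]).all()

    def test_empty_cohort_raises(self):
        with pytest.raises(CohortError):
            aggregate_cohort([])
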