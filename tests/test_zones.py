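"""Occlusion masks and zone semantics against analytic shadows and brute force."""

from __future__ import annotations

import numpy as np
import pytest

from quadzone import ZoneLabel, classify_zones, extract_landmarks, make_incision, occluded_mask
from quadzone import _geometry as geom
from quadzone.errors import NoLandmarksError

from conftest import icosphere


def plane_grid(n=50, half=40.0):
    xs = np.linspace(-half, half, n)
    X, Y = np.meshgrid(xs, xs, indexing="ij")
    return np.stack([X.ravel(), Y.ravel(), np.zeros(X.size)], axis=-1)


def analytic_shadow(points, viewpoint, center, radius):
    """Segment viewpoint->point passes within ``radius`` of ``center``."""
    v = np.asarray(viewpoint, dtype=float)
    d = points - v
    ll = np.einsum("ij,ij->i", d, d)
    t = np.clip(np.einsum("ij,j->i", d, np.asarray(center) - v) / ll, 0, 1)
    closest = v + t[:, None] * d
    return np.linalg.norm(closest - np.asarray(center), axis=1) < radius


def shadow_margin(points, viewpoint, center, radius):
    """Distance of the sight segment from the sphere surface (signed)."""
    v = np.asarray(viewpoint, dtype=float)
    d = points - v
    ll = np.einsum("ij,ij->i", d, d)
    t = np.clip(np.einsum("ij,j->i", d, np.asarray(center) - v) / ll, 0, 1)
    closest = v + t[:, None] * d
    return np.linalg.norm(closest - np.asarray(center), axis=1) - radius


def brute_force_blocked(viewpoint, targets, mesh):
    """Exhaustive per-triangle open-segment test (independent loop oracle)."""
    v = np.asarray(viewpoint, dtype=float)
    out = np.zeros(len(targets), dtype=bool)
    tris = mesh.triangles
    for i, p in enumerate(targets):
        direction = p - v
        L = np.linalg.norm(direction)
        ts, _ = geom.ray_triangle_ts(v, direction / L, tris)
        out[i] = bool(np.any((ts > geom.RAY_EPS_MM) & (ts < L - geom.RAY_EPS_MM)))
    return out


CENTER = np.array([5.0, -3.0, 30.0])
RADIUS = 10.0
VIEWPOINT = np.array([0.0, 0.0, 100.0])


@pytest.fixture(scope="module")
def sphere():
    return icosphere(radius=RADIUS, center=CENTER, subdivisions=3)


@pytest.fixture(scope="module")
def shells():
    return (
        icosphere(radius=RADIUS, center=CENTER, subdivisions=3),
        icosphere(radius=RADIUS + 3.0, center=CENTER, subdivisions=3),
    )


class TestOccludedMask:
    def test_point_behind_sphere_blocked_lateral_clear(self, sphere):
        behind = CENTER + (CENTER - VIEWPOINT) * 0.8
        behind[2] = 0.0
        clear = np.array([35.0, 35.0, 0.0])
        mask = occluded_mask(np.stack([behind, clear]), sphere, VIEWPOINT)
        assert mask.tolist() == [True, False]

    def test_matches_bruteforce_exactly_on_grid(self, sphere):
        pts = plane_grid()
        mask = occluded_mask(pts, sphere, VIEWPOINT)
        np.testing.assert_array_equal(mask, brute_force_blocked(VIEWPOINT, pts, sphere))

    def test_matches_analytic_shadow_conic_away_from_boundary(self, sphere):
        # The shadow of the sphere on the plane is the conic projection of
        # its silhouette; disagreement is confined to a band around the
        # boundary of one grid-edge width (the icosphere is inscribed).
        pts = plane_grid()
        mask = occluded_mask(pts, sphere, VIEWPOINT)
        margin = shadow_margin(pts, VIEWPOINT, CENTER, RADIUS)
        edge = 80.0 / 49  # grid spacing
        interior = margin < -edge / 2
        exterior = margin > edge / 2
        assert mask[interior].all()
        assert not mask[exterior].any()

    def test_viewpoint_on_entry_point_rejected(self, sphere):
        with pytest.raises(ValueError):
            occluded_mask(np.array([VIEWPOINT]), sphere, VIEWPOINT)

    def test_grid_broadphase_agrees_with_chunked_numpy(self, sphere):
        # The accelerated path (uniform-grid DDA) must agree with the plain
        # chunked Moller-Trumbore evaluation exactly.
        pts = plane_grid(n=30)
        tris = sphere.triangles
        plain = geom.segments_blocked(VIEWPOINT, pts, tris)
        gridded = geom.segments_blocked(
            VIEWPOINT, pts, tris, grid=geom.build_triangle_grid(tris)
        )
        np.testing.assert_array_equal(plain, gridded)


class TestClassifyZones:
    def test_no_occluder_in_sight_all_safe(self, shells):
        ap = make_incision([60, 0, 100], [60, 30, 100], 3)
        pts = plane_grid(n=10, half=5.0) + np.array([60.0, 0.0, 0.0])
        zm = classify_zones(pts, shells[0], shells[1], ap)
        assert (zm.labels == int(ZoneLabel.ABS_SAFE)).all()

    def test_two_viewpoint_set_algebra(self, shells):
        """ABS_DANGER = intersection of per-viewpoint inner-shell shadows;
        ABS_SAFE = union of per-viewpoint outer-shell shadow complements."""
        inner, outer = shells
        v1 = np.array([-40.0, 0.0, 100.0])
        v2 = np.array([40.0, 0.0, 100.0])
        ap = make_incision(v1, v2, 2)
        pts = plane_grid()
        zm = classify_zones(pts, inner, outer, ap)

        edge = 80.0 / 49
        m_in = [shadow_margin(pts, v, CENTER, RADIUS) for v in (v1, v2)]
        m_out = [shadow_margin(pts, v, CENTER, RADIUS + 3.0) for v in (v1, v2)]
        clear = lambda ms: np.maximum(np.abs(ms[0]), np.abs(ms[1])) > 0  # noqa: E731
        off_boundary = (
            (np.abs(m_in[0]) > edge) & (np.abs(m_in[1]) > edge)
            & (np.abs(m_out[0]) > edge) & (np.abs(m_out[1]) > edge)
        )
        exp_danger = (m_in[0] < 0) & (m_in[1] < 0)
        exp_safe = (m_out[0] > 0) | (m_out[1] > 0)
        got = zm.labels[off_boundary]
        assert np.array_equal(got == int(ZoneLabel.ABS_DANGER), exp_danger[off_boundary])
        assert np.array_equal(got == int(ZoneLabel.ABS_SAFE), exp_safe[off_boundary])
        rel = (~exp_danger & ~exp_safe)[off_boundary]
        assert np.array_equal(got == int(ZoneLabel.REL_DANGER), rel)

    def test_shell_nesting_implies_zone_nesting(self, shells):
        ap = make_incision([-40, 0, 100], [40, 0, 100], 5)
        pts = plane_grid(n=30)
        zm = classify_zones(pts, shells[0], shells[1], ap)
        # per-viewpoint: occlusion by the inner shell implies outer-shell occlusion
        assert not (zm.masks_absolute & ~zm.masks_margin).any()
        # hence region A (ABS_DANGER) is inside region B (complement of ABS_SAFE)
        assert not (zm.dangerous_mask("absolute") & ~zm.dangerous_mask("margin")).any()

    def test_viewpoint_monotonicity(self, shells):
        # More viewpoints: ABS_DANGER can only shrink, ABS_SAFE only grow.
        pts = plane_grid(n=30)
        p, q = np.array([-40.0, 0, 100.0]), np.array([40.0, 0, 100.0])
        zm3 = classify_zones(pts, shells[0], shells[1], make_incision(p, q, 3))
        zm5 = classify_zones(pts, shells[0], shells[1], make_incision(p, q, 5))
        assert not (zm5.dangerous_mask("absolute") & ~zm3.dangerous_mask("absolute")).any()
        safe3 = zm3.labels == int(ZoneLabel.ABS_SAFE)
        safe5 = zm5.labels == int(ZoneLabel.ABS_SAFE)
        assert not (safe3 & ~safe5).any()

    def test_union_quantifier_grows_dangerous_zone(self, shells):
        pts = plane_grid(n=30)
        ap = make_incision([-40, 0, 100], [40, 0, 100], 3)
        inter = classify_zones(pts, shells[0], shells[1], ap, quantifier="intersection")
        union = classify_zones(pts, shells[0], shells[1], ap, quantifier="union")
        assert not (inter.dangerous_mask("absolute") & ~union.dangerous_mask("absolute")).any()

    def test_unknown_quantifier_rejected(self, shells):
        ap = make_incision([-40, 0, 100], [40, 0, 100], 2)
        with pytest.raises(ValueError):
            classify_zones(plane_grid(n=5), shells[0], shells[1], ap, quantifier="sometimes")


class TestViewpointConvergence:
    def test_doubling_viewpoints_changes_zones_below_one_percent(self, default_phantom):
        """With the default 21-viewpoint aperture the zones have converged:
        42 viewpoints move fewer than 1% of the vertices in each zone."""
        subj, cfg, result, _ = default_phantom
        pts = result.zonemap.points
        shells = (result.zonemap.shell_absolute, result.zonemap.shell_margin)
        p, q = subj.landmarks.incision_proximal, subj.landmarks.incision_distal
        counts = {}
        for n in (21, 42):
            zm = classify_zones(pts, shells[0], shells[1], make_incision(p, q, n))
            counts[n] = zm.counts()
        for label in counts[21]:
            a, b = counts[21][label], counts[42][label]
            assert abs(a - b) < 0.01 * len(pts), (label, a, b)


class TestExtractLandmarks:
    def test_all_safe_zonemap_raises(self, mini_phantom):
        subj, cfg, result, truth = mini_phantom
        zm = result.zonemap
        # A zonemap whose masks are all clear has no dangerous zone.
        import copy

        empty = copy.copy(zm)
        empty.masks_absolute = np.zeros_like(zm.masks_absolute)
        empty.masks_margin = np.zeros_like(zm.masks_margin)
        with pytest.raises(NoLandmarksError):
            extract_landmarks(empty, subj.landmarks.brim, subj.landmarks.obturator_canal)

    def test_landmarks_near_truth_on_mini_phantom(self, mini_phantom):
        subj, cfg, result, truth = mini_phantom
        edge = subj.spec.mesh_resolution
        for d, zl in result.landmarks.items():
            tl = truth.landmarks[d]
            for nm in "EFGH":
                err = np.linalg.norm(getattr(zl, nm) - getattr(tl, nm))
                assert err <= 2 * edge, f"{nm} at d={d}: {err:.2f} mm"
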