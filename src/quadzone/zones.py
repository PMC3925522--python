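"""Safe / dangerous zone classification on the quadrilateral surface.

A candidate entry point is *occluded* from a viewpoint when the straight
segment between them crosses the offset acetabular shell — a screw driven
along that sight line would come closer to the articular surface than the
shell's clearance. With the viewpoints restricted to the Stoppa incision:

* **absolutely dangerous** — occluded by the 2.95 mm shell from *every*
  admissible viewpoint: no feasible trajectory respects even the minimal
  clearance (region A);
* **absolutely safe** — clear of the 6 mm shell from *at least one*
  viewpoint: some feasible trajectory keeps the full clearance plus the 3 mm
  error margin (the complement of region B);
* **relatively dangerous** — everything in between: reachable within
  2.95 mm clearance from some direction but never with the 6 mm margin.

The all/some quantifier pair is the default; an alternative union reading
(dangerous when occluded from *any* viewpoint) is exposed via
``quantifier="union"`` for sensitivity analyses.

Landmarks E, F, G, H delimit the dangerous region: E and F are the occlusion
boundary points on the pelvic brim seen from the distal and proximal incision
ends (farthest from / nearest to the obturator canal respectively); G is the
dangerous-zone point farthest from the obturator canal, H the one farthest
from the brim.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np

from . import _geometry as geom
from .errors import NoLandmarksError
from .incision import IncisionAperture
from .mesh import TriangleMesh

#: Brim polylines are resampled at most this far apart (mm) before occlusion
#: is evaluated on them; the pipeline tightens this with mesh resolution.
DEFAULT_BRIM_SPACING = 0.5

#: Objective slack (mm) defining the near-optimal plateau of G and H. The
#: distance-to-canal / distance-to-brim objectives are extremely flat along
#: the zone boundary (sub-micrometre drop over a millimetre), so the raw
#: argmax is ill-conditioned; the centroid of the plateau is stable.
PLATEAU_EPS_MM = 0.05


class ZoneLabel(IntEnum):
    ABS_SAFE = 0
    REL_DANGER = 1
    ABS_DANGER = 2


@dataclass
class ZoneMap:
    """Per-entry-point zone labels plus the per-viewpoint occlusion masks and
    the shells they were computed from (retained for landmark extraction and
    diagnostics)."""

    points: np.ndarray                 # (N, 3) analyzed entry points
    labels: np.ndarray                 # (N,) ZoneLabel values
    masks_absolute: np.ndarray         # (V, N) occlusion by the 2.95 mm shell
    masks_margin: np.ndarray           # (V, N) occlusion by the 6 mm shell
    aperture: IncisionAperture
    shell_absolute: TriangleMesh
    shell_margin: TriangleMesh
    quantifier: str = "intersection"
    region_vertices: np.ndarray | None = None  # indices into the source mesh

    def dangerous_mask(self, which: str = "absolute") -> np.ndarray:
        """Aggregate dangerous region for one shell under the quantifier."""
        masks = self.masks_absolute if which == "absolute" else self.masks_margin
        return masks.all(axis=0) if self.quantifier == "intersection" else masks.any(axis=0)

    def counts(self) -> dict[str, int]:
        return {label.name: int((self.labels == label).sum()) for label in ZoneLabel}


@dataclass(frozen=True)
class ZoneLandmarks:
    E: np.ndarray
    F: np.ndarray
    G: np.ndarray
    H: np.ndarray

    def as_dict(self) -> dict[str, list[float]]:
        return {k: [float(x) for x in getattr(self, k)] for k in "EFGH"}


def occluded_mask(
    entry_points: np.ndarray,
    occluder: TriangleMesh,
    viewpoint: np.ndarray,
    closed_occluder: bool = False,
) -> np.ndarray:
    """True where the open segment viewpoint -> entry point crosses the
    occluder (the screw trajectory would breach the shell's clearance).

    ``closed_occluder=True`` enables back-face culling, exact for closed,
    outward-wound shells such as the offset surfaces.
    """
    pts = np.atleast_2d(np.asarray(entry_points, dtype=float))
    vp = np.asarray(viewpoint, dtype=float).reshape(3)
    if len(pts) and np.min(np.linalg.norm(pts - vp, axis=1)) < 1e-9:
        raise ValueError("viewpoint coincides with an entry point")
    grid = occluder.triangle_grid() if len(occluder.faces) >= 4096 else None
    return geom.segments_blocked(
        vp, pts, occluder.triangles, closed_occluder=closed_occluder, grid=grid
    )


def classify_zones(
    entry_points: np.ndarray,
    shell_absolute: TriangleMesh,
    shell_margin: TriangleMesh,
    aperture: IncisionAperture,
    quantifier: str = "intersection",
    region_vertices: np.ndarray | None = None,
) -> ZoneMap:
    """Label every entry point ABS_DANGER / REL_DANGER / ABS_SAFE.

    ``quantifier`` selects the aggregate over viewpoints for the dangerous
    region: ``"intersection"`` (default: dangerous only if occluded from all
    viewpoints) or ``"union"`` (dangerous if occluded from any viewpoint).
    """
    if quantifier not in ("intersection", "union"):
        raise ValueError(f"unknown quantifier {quantifier!r}")
    if aperture.n_viewpoints < 1:
        raise ValueError("aperture has no viewpoints")
    pts = np.atleast_2d(np.asarray(entry_points, dtype=float))
    closed_abs = shell_absolute.is_watertight
    closed_mar = shell_margin.is_watertight
    masks_abs = np.stack(
        [occluded_mask(pts, shell_absolute, v, closed_abs) for v in aperture.viewpoints]
    )
    masks_mar = np.stack(
        [occluded_mask(pts, shell_margin, v, closed_mar) for v in aperture.viewpoints]
    )

    zm = ZoneMap(
        points=pts,
        labels=np.zeros(len(pts), dtype=np.int64),
        masks_absolute=masks_abs,
        masks_margin=masks_mar,
        aperture=aperture,
        shell_absolute=shell_absolute,
        shell_margin=shell_margin,
        quantifier=quantifier,
        region_vertices=None if region_vertices is None else np.asarray(region_vertices),
    )
    danger_abs = zm.dangerous_mask("absolute")
    danger_mar = zm.dangerous_mask("margin")
    labels = np.full(len(pts), int(ZoneLabel.ABS_SAFE), dtype=np.int64)
    labels[danger_mar] = int(ZoneLabel.REL_DANGER)
    labels[danger_abs & danger_mar] = int(ZoneLabel.ABS_DANGER)
    zm.labels = labels
    return zm


def extract_landmarks(
    zonemap: ZoneMap,
    brim: np.ndarray,
    obturator_canal: np.ndarray,
    aperture: IncisionAperture | None = None,
    which: str = "absolute",
    brim_spacing: float = DEFAULT_BRIM_SPACING,
    tie_tol_mm: float = 1e-6,
    refine_step: float | None = None,
) -> ZoneLandmarks:
    """Extremal landmarks of one shell's dangerous region.

    E / F are evaluated on the brim curve itself (densified to
    ``brim_spacing``): E is the occluded brim point farthest from the
    obturator canal as seen from the *distal* incision end, F the occluded
    brim point nearest the canal as seen from the *proximal* end. G and H are
    the dangerous-zone entry points farthest from the canal and from the brim
    respectively; near-exact ties resolve to the smallest vertex index.

    ``refine_step`` (mm) enables a sub-vertex refinement of G and H: the
    occlusion predicate is re-evaluated on a fine local grid in the region's
    tangent plane around the winning vertex, so the landmark converges to the
    continuous extremum of the meshed zone rather than the nearest vertex.
    """
    if aperture is None:
        aperture = zonemap.aperture
    if len(np.asarray(brim)) < 2:
        raise ValueError("brim polyline needs at least 2 points")
    shell = zonemap.shell_absolute if which == "absolute" else zonemap.shell_margin
    canal = np.asarray(obturator_canal, dtype=float).reshape(3)

    danger = zonemap.dangerous_mask(which)
    if not danger.any():
        raise NoLandmarksError(f"dangerous zone for shell {which!r} is empty")
    dpts = zonemap.points[danger]

    dist_canal = np.linalg.norm(dpts - canal, axis=1)
    G = dpts[_argmax_tiebreak(dist_canal, tie_tol_mm)]

    brim_dense = geom.densify_polyline(np.asarray(brim, dtype=float), brim_spacing)
    dist_brim = geom.polyline_distances(dpts, brim_dense)
    H = dpts[_argmax_tiebreak(dist_brim, tie_tol_mm)]

    if refine_step is not None and refine_step > 0:
        G = _refine_extremal(
            zonemap, shell, aperture, G,
            lambda p: np.linalg.norm(p - canal, axis=1), refine_step,
        )
        H = _refine_extremal(
            zonemap, shell, aperture, H,
            lambda p: geom.polyline_distances(p, brim_dense), refine_step,
        )

    closed = shell.is_watertight
    distal_mask = occluded_mask(brim_dense, shell, aperture.viewpoints[-1], closed)
    if not distal_mask.any():
        raise NoLandmarksError("shell never occludes the brim from the distal incision end (E undefined)")
    occluded = brim_dense[distal_mask]
    E = occluded[int(np.argmax(np.linalg.norm(occluded - canal, axis=1)))]

    proximal_mask = occluded_mask(brim_dense, shell, aperture.viewpoints[0], closed)
    if not proximal_mask.any():
        raise NoLandmarksError("shell never occludes the brim from the proximal incision end (F undefined)")
    occluded = brim_dense[proximal_mask]
    F = occluded[int(np.argmin(np.linalg.norm(occluded - canal, axis=1)))]

    return ZoneLandmarks(E=E, F=F, G=G, H=H)


def _argmax_tiebreak(values: np.ndarray, tol: float) -> int:
    """Index of the maximum; among values within ``tol`` of it, the smallest
    index (deterministic under symmetric geometry)."""
    mx = float(values.max())
    return int(np.nonzero(values >= mx - tol)[0][0])


def _refine_extremal(
    zonemap: ZoneMap,
    shell: TriangleMesh,
    aperture: IncisionAperture,
    start: np.ndarray,
    objective,
    step: float,
) -> np.ndarray:
    """Local continuous refinement of an extremal dangerous-zone point.

    Evaluates the dangerous predicate (occluded under the zonemap's
    quantifier) on a ``step``-spaced grid in the region's tangent plane
    around ``start``, restricted to the footprint of the analyzed region
    (within one vertex spacing of an analyzed entry point), and returns the
    objective's argmax. Falls back to ``start`` if nothing qualifies.
    """
    from scipy.spatial import cKDTree

    pts = zonemap.points
    origin, normal = geom.fit_plane(pts[np.linalg.norm(pts - start, axis=1).argsort()[:64]])
    a = np.array([1.0, 0.0, 0.0]) if abs(normal[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(normal, a)
    u /= np.linalg.norm(u)
    v = np.cross(normal, u)

    tree = cKDTree(pts)
    nn = tree.query(np.atleast_2d(start), k=2)[0][0, 1]
    spacing = max(float(nn), step)
    closed = shell.is_watertight

    def best_around(centre: np.ndarray, half: float, grid: float) -> tuple[np.ndarray, float] | None:
        offs = np.arange(-half, half + grid / 2, grid)
        A, B = np.meshgrid(offs, offs, indexing="ij")
        cand = centre + A.ravel()[:, None] * u + B.ravel()[:, None] * v
        cand = cand - np.outer((cand - start) @ normal, normal)
        cand = cand[tree.query(cand, k=1)[0] <= 1.05 * spacing]
        if len(cand) == 0:
            return None
        masks = np.stack([occluded_mask(cand, shell, vp, closed) for vp in aperture.viewpoints])
        danger = masks.all(axis=0) if zonemap.quantifier == "intersection" else masks.any(axis=0)
        if not danger.any():
            return None
        vals = objective(cand[danger])
        i = int(np.argmax(vals))
        return cand[danger][i], float(vals[i])

    best, best_val = start, float(objective(start[None])[0])
    # Flat objectives let the discrete argmax slide along the zone boundary,
    # so sweep wide at half-vertex resolution first, then refine locally.
    coarse = best_around(start, 8.0 * spacing, spacing / 2.0)
    if coarse is not None and coarse[1] >= best_val:
        best, best_val = coarse
    fine = best_around(best, 1.2 * spacing, step)
    if fine is not None and fine[1] >= best_val:
        best, best_val = fine

    # Plateau centroid: average the near-optimal set, which is stable where
    # the raw argmax is not.
    half = max(3.0, 2.0 * spacing)
    offs = np.arange(-half, half + step / 2, step)
    A, B = np.meshgrid(offs, offs, indexing="ij")
    cand = best + A.ravel()[:, None] * u + B.ravel()[:, None] * v
    cand = cand - np.outer((cand - start) @ normal, normal)
    cand = cand[tree.query(cand, k=1)[0] <= 1.05 * spacing]
    if len(cand):
        masks = np.stack([occluded_mask(cand, shell, vp, closed) for vp in aperture.viewpoints])
        danger = masks.all(axis=0) if zonemap.quantifier == "intersection" else masks.any(axis=0)
        if danger.any():
            vals = objective(cand[danger])
            plateau = cand[danger][vals >= max(best_val, float(vals.max())) - PLATEAU_EPS_MM]
            if len(plateau):
                return plateau.mean(axis=0)
    return best
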