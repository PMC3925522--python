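"""Parametric hemipelvis phantoms with analytic ground truth.

The phantom emulates the anatomy the occlusion analysis needs, reduced to
shapes with closed-form geometry:

* the **quadrilateral plate**: a planar slab in z = 0 bounded above by the
  pelvic brim, laterally by the brim's chord ends and below by a straight
  edge, pierced by an elliptical obturator foramen;
* the **pelvic brim**: a circular arc in the plate plane;
* the **acetabular cup**: a spherical cap (centre above the plate, pole
  toward the incision) — sphericity buys exact shadow geometry; a seeded
  "lumpy" mode (``noise_sigma > 0``) exercises non-spherical robustness
  without analytic truth;
* the **Stoppa incision**: a longitudinal midline segment above the plate.

For the spherical cup every occlusion question has a closed form: a plate
point is hidden from a viewpoint by the shell of radius r + d exactly when
the viewpoint-to-point segment passes within r + d of the cup centre, and
the shadow boundary on the plate is a conic. :func:`analytic_truth`
evaluates those closed forms (with dense 1-D/2-D sampling refined well below
micrometre scale for the extremal landmarks) independently of the mesh
pipeline, providing the oracle for end-to-end recovery tests.

Default dimensions are plausible adult-scale anatomy (acetabular radius
24 mm, plate roughly 70 x 100 mm, flat brim arc of radius 150 mm crossing it
obliquely, an obliquely tilted 40 x 16 mm foramen, an 80 mm incision ~60 mm
above and medial to the plate); they are configuration, not measured values.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import _geometry as geom
from .errors import CohortError, NoIntersectionError, PhantomSpecError
from .incision import DEFAULT_N_VIEWPOINTS, IncisionAperture, make_incision
from .landmarks import LandmarkSet, save_landmarks
from .mesh import TriangleMesh, save_mesh
from .metrics import MM_PER_CM, MeasurementRecord
from .zones import ZoneLandmarks

#: Landmark polylines are emitted at (at most) this sample spacing, mm.
LANDMARK_SPACING = 0.5


@dataclass(frozen=True)
class PhantomSpec:
    """Full parametric description of one phantom subject (mm, degrees)."""

    # Acetabular cup (spherical cap). The cup sits mostly behind (lateral
    # to) the plate plane z = 0; only its apex region and the offset shells
    # protrude medially, which is what produces the paper-scale (few-cm)
    # dangerous zone rather than a full-sphere shadow.
    acetabulum_center: tuple[float, float, float] = (8.43, -15.33, -20.0)
    acetabulum_radius: float = 24.0
    cup_opening_axis: tuple[float, float, float] = (0.0, 0.0, -1.0)
    cap_half_angle_deg: float = 120.0
    # Pelvic brim: a flat circular arc running obliquely, near-longitudinal,
    # as the linea terminalis does in a Stoppa view.
    brim_center_x: float = -125.9
    brim_center_y: float = -51.3
    brim_radius: float = 150.0
    brim_apex_deg: float = 70.0
    brim_half_angle_deg: float = 26.0
    # Quadrilateral plate slab. The brim arc forms the plate's lateral
    # boundary; the remaining bounds are straight cuts.
    plate_x_min: float = -45.0
    plate_y_min: float = -62.0
    plate_y_max: float = 40.0
    plate_thickness: float = 4.0
    # Obturator foramen: ellipse in the plate plane. ``foramen_tilt_deg``
    # rotates the ellipse frame clockwise (negative = the long axis leans
    # up toward the acetabulum, as the real foramen's oblique axis does).
    foramen_center_x: float = 4.0
    foramen_center_y: float = -46.0
    foramen_semi_x: float = 20.0    # semi-axis along the tilted "width" axis
    foramen_semi_y: float = 8.0     # semi-axis along the tilted "height" axis
    foramen_tilt_deg: float = -24.0
    canal_angle_deg: float = 75.0   # rim parameter of the obturator canal point
    # Incision (skin level): longitudinal, medial to the plate, elevated
    incision_proximal: tuple[float, float, float] = (-80.0, 45.0, 60.0)
    incision_distal: tuple[float, float, float] = (-80.0, -35.0, 60.0)
    # Discretisation & reproducibility
    mesh_resolution: float = 1.0    # target edge length, mm
    random_seed: int = 0
    scale: float = 1.0
    noise_sigma: float = 0.0        # radial cup perturbation amplitude, mm
    side: str = "left"

    # -- derived scalar geometry (unscaled) -------------------------------

    @property
    def brim_center(self) -> np.ndarray:
        return np.array([self.brim_center_x, self.brim_center_y, 0.0])

    @property
    def plate_x_bounds(self) -> tuple[float, float]:
        """Lateral plate bounds: straight cut on the medial side, the brim
        arc's largest x on the lateral side."""
        th = np.radians(self.brim_half_angle_deg)
        arc = self.brim_point(np.linspace(-th, th, 721))
        return self.plate_x_min, float(arc[:, 0].max())

    @property
    def foramen_center(self) -> np.ndarray:
        return np.array([self.foramen_center_x, self.foramen_center_y, 0.0])

    def brim_point(self, theta: np.ndarray) -> np.ndarray:
        """Arc point(s) at angle theta (radians from the apex direction)."""
        theta = np.asarray(theta, dtype=float)
        ang = np.radians(self.brim_apex_deg) + theta
        return np.stack(
            [
                self.brim_center_x + self.brim_radius * np.sin(ang),
                self.brim_center_y + self.brim_radius * np.cos(ang),
                np.zeros_like(theta),
            ],
            axis=-1,
        )

    @property
    def foramen_axes(self) -> tuple[np.ndarray, np.ndarray]:
        """In-plane unit axes (width, height) of the tilted foramen ellipse."""
        phi = np.radians(self.foramen_tilt_deg)
        u = np.array([np.sin(phi), np.cos(phi), 0.0])       # "height" axis
        u_perp = np.array([np.cos(phi), -np.sin(phi), 0.0])  # "width" axis
        return u_perp, u

    def foramen_point(self, t: np.ndarray) -> np.ndarray:
        """Foramen rim point(s) at ellipse parameter t (radians)."""
        t = np.asarray(t, dtype=float)
        w, h = self.foramen_axes
        return (
            self.foramen_center[None, ...]
            + np.multiply.outer(self.foramen_semi_x * np.sin(t), w)
            + np.multiply.outer(self.foramen_semi_y * np.cos(t), h)
        ).reshape(t.shape + (3,) if t.shape else (3,))

    def foramen_top(self) -> np.ndarray:
        """Topmost (max-y) point of the foramen rim — the clinical 'top point
        of the obturator foramen' through which K's perpendicular is dropped."""
        w, h = self.foramen_axes
        ay = self.foramen_semi_x * w[1]
        by = self.foramen_semi_y * h[1]
        t = np.arctan2(ay, by)
        return self.foramen_point(t)

    def region_contains(self, xy: np.ndarray, margin: float = 0.0) -> np.ndarray:
        """Membership of (unscaled) plate-plane points in the quadrilateral
        region: inside the brim circle and lateral/bottom bounds, outside the
        foramen ellipse."""
        xy = np.atleast_2d(np.asarray(xy, dtype=float))[:, :2]
        bc = self.brim_center[:2]
        x_lo, x_hi = self.plate_x_bounds
        in_circle = np.linalg.norm(xy - bc, axis=1) <= self.brim_radius - margin
        in_x = (xy[:, 0] >= x_lo + margin) & (xy[:, 0] <= x_hi - margin)
        in_y = (xy[:, 1] >= self.plate_y_min + margin) & (xy[:, 1] <= self.plate_y_max - margin)
        w, h = self.foramen_axes
        rel = xy - self.foramen_center[:2]
        fw = (rel @ w[:2]) / (self.foramen_semi_x + margin)
        fh = (rel @ h[:2]) / (self.foramen_semi_y + margin)
        out_ellipse = fw**2 + fh**2 >= 1.0
        return in_circle & in_x & in_y & out_ellipse


def validate_spec(spec: PhantomSpec) -> None:
    """Raise :class:`PhantomSpecError` on geometrically infeasible specs."""
    if spec.acetabulum_radius <= 0:
        raise PhantomSpecError("acetabulum_radius must be positive")
    if spec.mesh_resolution <= 0 or spec.scale <= 0:
        raise PhantomSpecError("mesh_resolution and scale must be positive")
    if not 90.0 < spec.cap_half_angle_deg < 180.0:
        raise PhantomSpecError("cap_half_angle_deg must be in (90, 180)")
    if spec.brim_point(0.0)[1] <= spec.plate_y_min:
        raise PhantomSpecError("brim arc apex lies below the plate")
    # Foramen strictly inside the plate region (hole margin 1 mm).
    rim = spec.foramen_point(np.linspace(0, 2 * np.pi, 96, endpoint=False))[:, :2]
    bc = spec.brim_center[:2]
    x_lo, x_hi = spec.plate_x_bounds
    ok = (
        (np.linalg.norm(rim - bc, axis=1) < spec.brim_radius - 1.0)
        & (rim[:, 0] > x_lo + 1.0)
        & (rim[:, 0] < x_hi - 1.0)
        & (rim[:, 1] > spec.plate_y_min + 1.0)
        & (rim[:, 1] < spec.plate_y_max - 1.0)
    )
    if not ok.all():
        raise PhantomSpecError("foramen is not strictly inside the plate region")
    # Cup adjacent to the plate: its pole must reach the plate plane (the
    # cup sits mostly lateral/behind the plate, its apex region protruding
    # medially), but not tower far above it.
    pole_z = spec.acetabulum_center[2] + spec.acetabulum_radius
    if pole_z <= 0:
        raise PhantomSpecError("acetabular cup lies entirely behind the plate plane")
    if pole_z > 2 * spec.acetabulum_radius:
        raise PhantomSpecError("acetabular cup is not adjacent to the plate")
    # Incision clear of the cup with generous shell headroom.
    c = np.asarray(spec.acetabulum_center)
    for p in (spec.incision_proximal, spec.incision_distal):
        if np.linalg.norm(np.asarray(p) - c) <= spec.acetabulum_radius + 10.0:
            raise PhantomSpecError("incision endpoint too close to the acetabular cup")
    if np.allclose(spec.incision_proximal, spec.incision_distal):
        raise PhantomSpecError("incision endpoints coincide")


@dataclass
class PhantomSubject:
    """One generated phantom: meshes, landmarks and the incision aperture."""

    subject_id: str
    spec: PhantomSpec
    pelvis: TriangleMesh          # watertight plate slab with foramen hole
    acetabulum: TriangleMesh      # open spherical cap (articular sub-surface)
    landmarks: LandmarkSet
    aperture: IncisionAperture


def generate_phantom(
    spec: PhantomSpec,
    subject_id: str = "phantom",
    n_viewpoints: int = DEFAULT_N_VIEWPOINTS,
) -> PhantomSubject:
    """Deterministically mesh a phantom spec.

    The plate slab is a watertight extrusion of the triangulated region; the
    acetabular cap is an open latitude/longitude triangulation of the
    spherical cap with vertices exactly on the sphere (or radially perturbed
    by a smooth seeded field when ``noise_sigma > 0``).
    """
    validate_spec(spec)
    s = spec.scale
    plate = _plate_slab(spec)
    cap = _cup_cap(spec)
    plate = TriangleMesh(plate.vertices * s, plate.faces, name=f"{subject_id}_pelvis")
    cap = TriangleMesh(cap.vertices * s, cap.faces, name=f"{subject_id}_acetabulum")

    th = np.radians(spec.brim_half_angle_deg)
    n_brim = int(np.ceil(2 * th * spec.brim_radius * s / LANDMARK_SPACING)) + 1
    brim = spec.brim_point(np.linspace(-th, th, max(n_brim, 2))) * s

    per = 2 * np.pi * max(spec.foramen_semi_x, spec.foramen_semi_y) * s
    n_rim = int(np.ceil(per / LANDMARK_SPACING)) + 1
    ts = np.linspace(0.0, 2 * np.pi, max(n_rim, 8))
    rim = spec.foramen_point(ts) * s

    region = _region_polygon(spec) * s
    lm = LandmarkSet(
        brim=brim,
        foramen_rim=rim,
        obturator_canal=spec.foramen_point(np.radians(spec.canal_angle_deg)) * s,
        foramen_top=spec.foramen_top() * s,
        incision_proximal=np.asarray(spec.incision_proximal, dtype=float) * s,
        incision_distal=np.asarray(spec.incision_distal, dtype=float) * s,
        region_polygon=region,
        side=spec.side,
        meta={"generator": "quadzone.phantom", "seed": spec.random_seed},
    )
    if spec.side == "right":
        lm = dataclasses.replace(lm, side="left").mirrored_x()
        lm.side = "right"
        plate = TriangleMesh(lm_mirror_vertices(plate.vertices), plate.faces[:, ::-1], plate.name)
        cap = TriangleMesh(lm_mirror_vertices(cap.vertices), cap.faces[:, ::-1], cap.name)
    aperture = make_incision(lm.incision_proximal, lm.incision_distal, n_viewpoints)
    return PhantomSubject(subject_id, spec, plate, cap, lm, aperture)


def lm_mirror_vertices(v: np.ndarray) -> np.ndarray:
    out = np.array(v, copy=True)
    out[:, 0] *= -1
    return out


def write_subject(subject: PhantomSubject, out_dir: str | Path) -> dict[str, Path]:
    """Emit the pipeline's input contract: two STLs, landmark JSON, spec YAML."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "pelvis": save_mesh(subject.pelvis, out / "pelvis.stl"),
        "acetabulum": save_mesh(subject.acetabulum, out / "acetabulum.stl"),
        "landmarks": save_landmarks(subject.landmarks, out / "landmarks.json"),
    }
    spec_path = out / "phantom_spec.yaml"
    spec_path.write_text(yaml.safe_dump(spec_to_dict(subject.spec), sort_keys=True))
    paths["spec"] = spec_path
    return paths


def spec_to_dict(spec: PhantomSpec) -> dict:
    d = dataclasses.asdict(spec)
    return {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}


def spec_from_dict(d: dict) -> PhantomSpec:
    kwargs = {
        k: (tuple(v) if isinstance(v, list) else v)
        for k, v in d.items()
        if k in {f.name for f in dataclasses.fields(PhantomSpec)}
    }
    return PhantomSpec(**kwargs)


# ---------------------------------------------------------------------------
# meshing internals


def _plate_slab(spec: PhantomSpec) -> TriangleMesh:
    """Triangulate the plate region on a grid and extrude to a closed slab."""
    h = spec.mesh_resolution
    x_lo, x_hi = spec.plate_x_bounds
    xs = np.arange(x_lo, x_hi + h / 2, h)
    ys = np.arange(spec.plate_y_min, spec.plate_y_max + h / 2, h)
    nx, ny = len(xs), len(ys)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    verts2 = np.stack([X.ravel(), Y.ravel()], axis=-1)

    idx = np.arange(nx * ny).reshape(nx, ny)
    a = idx[:-1, :-1].ravel()
    b = idx[1:, :-1].ravel()
    c = idx[1:, 1:].ravel()
    d = idx[:-1, 1:].ravel()
    # Alternate the cell diagonal for isotropy.
    ii, jj = np.meshgrid(np.arange(nx - 1), np.arange(ny - 1), indexing="ij")
    flip = ((ii + jj) % 2 == 0).ravel()
    tris = np.where(
        flip[:, None, None],
        np.stack([np.stack([a, b, c], -1), np.stack([a, c, d], -1)], 1),
        np.stack([np.stack([a, b, d], -1), np.stack([b, c, d], -1)], 1),
    ).reshape(-1, 3)

    inside = spec.region_contains(verts2)
    keep = inside[tris].all(axis=1)
    cent = verts2[tris].mean(axis=1)
    keep &= spec.region_contains(cent)
    tris = tris[keep]
    if len(tris) == 0:
        raise PhantomSpecError("plate region too small for the requested resolution")

    used = np.unique(tris)
    remap = -np.ones(nx * ny, dtype=np.intp)
    remap[used] = np.arange(len(used))
    tris = remap[tris]
    top = np.column_stack([verts2[used], np.zeros(len(used))])
    return _extrude_patch(top, tris, spec.plate_thickness)


def _extrude_patch(top_vertices: np.ndarray, faces: np.ndarray, thickness: float) -> TriangleMesh:
    """Close an open planar patch into a watertight slab of given thickness
    (extruded along -z): bottom copy with flipped faces plus boundary walls."""
    nv = len(top_vertices)
    bottom = top_vertices.copy()
    bottom[:, 2] -= thickness
    verts = np.vstack([top_vertices, bottom])
    bottom_faces = faces[:, ::-1] + nv

    edges = np.vstack([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    key = np.sort(edges, axis=1)
    _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
    boundary = edges[counts[inv] == 1]  # directed as in the top faces
    walls = []
    for v0, v1 in boundary:
        # Outward-consistent winding: top edge (v0 -> v1) belongs to a CCW top
        # face, so the wall quad (v1, v0, v0+nv, v1+nv) faces outward.
        walls.append([v1, v0, v0 + nv])
        walls.append([v1, v0 + nv, v1 + nv])
    all_faces = np.vstack([faces, bottom_faces, np.asarray(walls, dtype=np.intp)])
    return TriangleMesh(verts, all_faces, name="plate")


def _cup_cap(spec: PhantomSpec) -> TriangleMesh:
    """Latitude/longitude triangulation of the spherical cap."""
    c = np.asarray(spec.acetabulum_center, dtype=float)
    r = spec.acetabulum_radius
    pole = -np.asarray(spec.cup_opening_axis, dtype=float)
    pole = pole / np.linalg.norm(pole)
    # Orthonormal frame around the pole.
    a = np.array([1.0, 0.0, 0.0]) if abs(pole[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(pole, a)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(pole, e1)

    phi_max = np.radians(spec.cap_half_angle_deg)
    n_rings = max(3, int(np.ceil(phi_max * r / spec.mesh_resolution)))
    m = max(8, int(np.ceil(2 * np.pi * r / spec.mesh_resolution)))
    thetas = np.linspace(0.0, 2 * np.pi, m, endpoint=False)

    verts = [c + r * pole]
    rings = []
    for i in range(1, n_rings + 1):
        phi = phi_max * i / n_rings
        ring = (
            c
            + r * np.cos(phi) * pole
            + r * np.sin(phi) * (np.cos(thetas)[:, None] * e1 + np.sin(thetas)[:, None] * e2)
        )
        rings.append(np.arange(len(verts), len(verts) + m))
        verts.extend(ring)
    verts = np.asarray(verts)

    faces = []
    first = rings[0]
    for j in range(m):
        faces.append([0, first[j], first[(j + 1) % m]])
    for i in range(len(rings) - 1):
        r0, r1 = rings[i], rings[i + 1]
        for j in range(m):
            j2 = (j + 1) % m
            faces.append([r0[j], r1[j], r1[j2]])
            faces.append([r0[j], r1[j2], r0[j2]])
    faces = np.asarray(faces, dtype=np.intp)

    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.random_seed)
        rel = verts - c
        rho = np.linalg.norm(rel, axis=1)
        phi = np.arccos(np.clip(rel @ pole / rho, -1, 1))
        theta = np.arctan2(rel @ e2, rel @ e1)
        bump = np.zeros(len(verts))
        for k in range(1, 4):
            ak, pk = rng.normal(), rng.uniform(0, 2 * np.pi)
            bk, qk = rng.normal(), rng.uniform(0, 2 * np.pi)
            bump += (ak * np.cos(k * theta + pk) + bk) * np.sin(k * phi + qk) / k
        bump *= spec.noise_sigma / max(np.abs(bump).max(), 1e-9)
        verts = c + rel * ((rho + bump) / rho)[:, None]

    return TriangleMesh(verts, faces, name="acetabulum")


def _region_polygon(spec: PhantomSpec) -> np.ndarray:
    """Closed outer boundary of the quadrilateral region (z = 0): brim arc
    left-to-right, then down the lateral edges and along the bottom."""
    th = np.radians(spec.brim_half_angle_deg)
    n = max(64, int(np.ceil(2 * th * spec.brim_radius / LANDMARK_SPACING)))
    arc = spec.brim_point(np.linspace(-th, th, n))
    x_lo, _ = spec.plate_x_bounds
    y0, y1 = spec.plate_y_min, spec.plate_y_max
    keep = (arc[:, 1] >= y0) & (arc[:, 1] <= y1)
    arc = arc[keep]
    if len(arc) < 2:
        raise PhantomSpecError("brim arc does not cross the plate's y extent")
    head = np.array([[x_lo, y1, 0.0]])
    tail = np.array([[arc[-1, 0], y0, 0.0], [x_lo, y0, 0.0]])
    poly = np.vstack([head, arc, tail, head])
    return poly


# ---------------------------------------------------------------------------
# analytic truth


@dataclass
class PhantomTruth:
    """Closed-form occlusion geometry of a (noise-free) phantom.

    ``landmarks[d]`` and ``records[d]`` hold the exact E/F/G/H and the six
    distances for shell offset ``d``; ``shadow_conics[(i, d)]`` the implicit
    conic coefficients (A, B, C, D, E, F) of the silhouette-cone boundary of
    viewpoint ``i`` on the plate plane: the infinite sight line through a
    plate point passes within r + d of the cup centre iff
    A x^2 + B xy + C y^2 + D x + E y + F > 0 (and the point lies in front of
    the viewpoint). :meth:`occluded` uses the sight *segment*, which in
    addition truncates at the plate.
    """

    spec: PhantomSpec
    offsets: tuple[float, ...]
    aperture: IncisionAperture
    quantifier: str
    landmarks: dict[float, ZoneLandmarks]
    records: dict[float, MeasurementRecord]
    shadow_conics: dict[tuple[int, float], tuple[float, float, float, float, float, float]]

    # -- membership predicates (vectorised over points) -------------------

    def occluded(self, points: np.ndarray, viewpoint: np.ndarray, d: float) -> np.ndarray:
        """True where the segment viewpoint -> point crosses the offset sphere."""
        c = np.asarray(self.spec.acetabulum_center, dtype=float) * self.spec.scale
        R = self.spec.acetabulum_radius * self.spec.scale + d
        return _segment_within(np.asarray(viewpoint, float), np.atleast_2d(points), c, R)

    def dangerous(self, points: np.ndarray, d: float) -> np.ndarray:
        masks = np.stack([self.occluded(points, v, d) for v in self.aperture.viewpoints])
        return masks.all(axis=0) if self.quantifier == "intersection" else masks.any(axis=0)


def _segment_within(v: np.ndarray, points: np.ndarray, c: np.ndarray, R: float) -> np.ndarray:
    """Distance from c to each segment [v, p] below R (exact)."""
    d = points - v
    ll = np.einsum("ij,ij->i", d, d)
    t = np.clip(np.einsum("ij,j->i", d, c - v) / np.maximum(ll, 1e-300), 0.0, 1.0)
    closest = v + t[:, None] * d
    return np.linalg.norm(closest - c, axis=1) < R


def analytic_truth(
    spec: PhantomSpec,
    offsets: tuple[float, ...] = (2.95, 6.0),
    aperture: IncisionAperture | None = None,
    quantifier: str = "intersection",
) -> PhantomTruth:
    """Exact occlusion zones, landmarks and measurements for a spherical-cup
    phantom (raises for lumpy cups, which have no closed form)."""
    if spec.noise_sigma > 0:
        raise PhantomSpecError("analytic truth requires a noise-free (spherical) cup")
    validate_spec(spec)
    if aperture is None:
        s = spec.scale
        aperture = make_incision(
            np.asarray(spec.incision_proximal) * s, np.asarray(spec.incision_distal) * s
        )
    s = spec.scale
    c = np.asarray(spec.acetabulum_center, dtype=float) * s
    r = spec.acetabulum_radius * s
    for d in offsets:
        for v in aperture.viewpoints:
            if np.linalg.norm(v - c) <= r + d:
                raise PhantomSpecError(f"viewpoint inside the offset sphere (d={d}); truth undefined")

    conics = {}
    for i, v in enumerate(aperture.viewpoints):
        for d in offsets:
            conics[(i, float(d))] = _shadow_conic(v, c, r + d)

    truth = PhantomTruth(
        spec=spec,
        offsets=tuple(float(d) for d in offsets),
        aperture=aperture,
        quantifier=quantifier,
        landmarks={},
        records={},
        shadow_conics=conics,
    )
    for d in offsets:
        lmk = _truth_landmarks(spec, truth, float(d))
        truth.landmarks[float(d)] = lmk
        truth.records[float(d)] = _truth_record(spec, lmk, float(d))
    return truth


def _shadow_conic(v: np.ndarray, c: np.ndarray, R: float) -> tuple[float, ...]:
    """Implicit conic of the sphere's shadow boundary on z = 0 from viewpoint
    v: ((p - v) . axis)^2 - cos^2(alpha) |p - v|^2 = 0."""
    axis = c - v
    dist = np.linalg.norm(axis)
    axis = axis / dist
    k = 1.0 - (R / dist) ** 2  # cos^2 alpha
    ax, ay, az = axis
    vx, vy, vz = v
    u0 = -ax * vx - ay * vy - az * vz
    A = ax**2 - k
    B = 2 * ax * ay
    C = ay**2 - k
    D = 2 * ax * u0 + 2 * k * vx
    E = 2 * ay * u0 + 2 * k * vy
    F = u0**2 - k * (vx**2 + vy**2 + vz**2)
    return (float(A), float(B), float(C), float(D), float(E), float(F))


def _truth_landmarks(spec: PhantomSpec, truth: PhantomTruth, d: float) -> ZoneLandmarks:
    s = spec.scale
    canal = spec.foramen_point(np.radians(spec.canal_angle_deg)) * s
    vp_prox = truth.aperture.viewpoints[0]
    vp_dist = truth.aperture.viewpoints[-1]

    # E / F: extremal occluded points of the brim arc (dense 1-D sampling,
    # ~0.001 mm spacing — far below any pipeline tolerance).
    th = np.radians(spec.brim_half_angle_deg)
    n = max(int(np.ceil(2 * th * spec.brim_radius * s / 0.001)), 20001)
    brim = spec.brim_point(np.linspace(-th, th, n)) * s
    occ_dist = truth.occluded(brim, vp_dist, d)
    occ_prox = truth.occluded(brim, vp_prox, d)
    if not occ_dist.any() or not occ_prox.any():
        raise PhantomSpecError(f"shell d={d} never occludes the brim; E/F truth undefined")
    dist_canal = np.linalg.norm(brim - canal, axis=1)
    E = brim[occ_dist][int(np.argmax(dist_canal[occ_dist]))]
    F = brim[occ_prox][int(np.argmin(dist_canal[occ_prox]))]

    # G / H: extremal points of the dangerous region, coarse grid + local
    # refinement to ~0.002 mm.
    x_lo, x_hi = (b * s for b in spec.plate_x_bounds)
    y0, y1 = spec.plate_y_min * s, spec.plate_y_max * s
    G = _maximize_over_region(spec, truth, d, lambda p: np.linalg.norm(p - canal, axis=1), x_lo, x_hi, y0, y1)
    H = _maximize_over_region(spec, truth, d, lambda p: _arc_distance(spec, p), x_lo, x_hi, y0, y1)
    return ZoneLandmarks(E=E, F=F, G=G, H=H)


def _maximize_over_region(spec, truth, d, objective, x_lo, x_hi, y0, y1, coarse=0.2, fine=0.002):
    def best_on_grid(xs, ys):
        X, Y = np.meshgrid(xs, ys, indexing="ij")
        pts = np.stack([X.ravel(), Y.ravel(), np.zeros(X.size)], axis=-1)
        ok = spec.region_contains(pts[:, :2] / spec.scale)
        ok[ok] &= truth.dangerous(pts[ok], d)
        if not ok.any():
            return None, -np.inf
        vals = objective(pts[ok])
        i = int(np.argmax(vals))
        return pts[ok][i], float(vals[i])

    p, _ = best_on_grid(np.arange(x_lo, x_hi + coarse, coarse), np.arange(y0, y1 + coarse, coarse))
    if p is None:
        raise PhantomSpecError(f"dangerous region empty for shell d={d}; G/H truth undefined")
    for step, half in ((0.02, 0.25), (fine, 0.025)):
        q, _ = best_on_grid(
            np.arange(p[0] - half, p[0] + half + step, step),
            np.arange(p[1] - half, p[1] + half + step, step),
        )
        if q is not None:
            p = q

    # Same plateau-centroid tie-break as the pipeline's landmark extraction:
    # the argmax is ill-conditioned along the flat zone boundary, its
    # near-optimal set is not.
    from .zones import PLATEAU_EPS_MM

    half, step = 3.0, 0.02
    xs = np.arange(p[0] - half, p[0] + half + step, step)
    ys = np.arange(p[1] - half, p[1] + half + step, step)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    pts = np.stack([X.ravel(), Y.ravel(), np.zeros(X.size)], axis=-1)
    ok = spec.region_contains(pts[:, :2] / spec.scale)
    ok[ok] &= truth.dangerous(pts[ok], d)
    vals = objective(pts[ok])
    plateau = pts[ok][vals >= float(vals.max()) - PLATEAU_EPS_MM]
    return plateau.mean(axis=0)


def _arc_distance(spec: PhantomSpec, points: np.ndarray) -> np.ndarray:
    """Exact distance from plate points to the brim arc (circle restricted to
    its angular span; outside the span: distance to the nearer endpoint)."""
    s = spec.scale
    bc = spec.brim_center * s
    R = spec.brim_radius * s
    th = np.radians(spec.brim_half_angle_deg)
    rel = np.atleast_2d(points) - bc
    ang = np.arctan2(rel[:, 0], rel[:, 1]) - np.radians(spec.brim_apex_deg)
    on_arc = np.abs(ang) <= th
    d_circle = np.abs(np.linalg.norm(rel[:, :2], axis=1) - R)
    ends = spec.brim_point(np.array([-th, th])) * s
    d_ends = np.minimum(
        np.linalg.norm(points - ends[0], axis=1), np.linalg.norm(points - ends[1], axis=1)
    )
    return np.where(on_arc, d_circle, d_ends)


def _truth_record(spec: PhantomSpec, lmk: ZoneLandmarks, d: float) -> MeasurementRecord:
    """Closed-form K, M, N, P, Q and the six distances for exact landmarks."""
    s = spec.scale
    bc = spec.brim_center * s
    Rb = spec.brim_radius * s
    fc = spec.foramen_center * s
    a, b = spec.foramen_semi_x * s, spec.foramen_semi_y * s
    w_ax, h_ax = spec.foramen_axes
    ft = spec.foramen_top() * s

    def radial_foot(p: np.ndarray) -> np.ndarray:
        rel = p - bc
        return bc + Rb * rel / np.linalg.norm(rel)

    def parallel_hit(p: np.ndarray) -> np.ndarray:
        rel = p - bc
        rad = rel / np.linalg.norm(rel)
        t = np.array([rad[1], -rad[0], 0.0])  # in-plane tangent of the brim circle
        # Solve |(p + s t - fc)| = 1 in the tilted, axis-normalised ellipse frame.
        dp = p - fc
        wx, wy = (dp @ w_ax) / a, (dp @ h_ax) / b
        tx, ty = (t @ w_ax) / a, (t @ h_ax) / b
        A = tx**2 + ty**2
        B = 2 * (wx * tx + wy * ty)
        C = wx**2 + wy**2 - 1.0
        disc = B**2 - 4 * A * C
        if disc < 0:
            raise NoIntersectionError("brim-parallel line misses the foramen ellipse")
        roots = (-B + np.array([-1.0, 1.0]) * np.sqrt(disc)) / (2 * A)
        sbest = roots[np.argmin(np.abs(roots))]
        return p + sbest * t

    K = radial_foot(ft)
    M = radial_foot(lmk.G)
    P = radial_foot(lmk.H)
    N = parallel_hit(lmk.G)
    Q = parallel_hit(lmk.H)

    def cm(p, q):
        return float(np.linalg.norm(p - q)) / MM_PER_CM

    return MeasurementRecord(
        subject_id="truth",
        offset_d=d,
        EK=cm(lmk.E, K),
        FK=cm(lmk.F, K),
        GM=cm(lmk.G, M),
        GN=cm(lmk.G, N),
        HP=cm(lmk.H, P),
        HQ=cm(lmk.H, Q),
        aux_points={n: [float(x) for x in p] for n, p in (("K", K), ("M", M), ("N", N), ("P", P), ("Q", Q))},
    )


# ---------------------------------------------------------------------------
# cohorts


_PERTURBED_FIELDS = (
    "acetabulum_radius",
    "brim_radius",
    "brim_center_y",
    "foramen_semi_x",
    "foramen_semi_y",
    "foramen_center_y",
    "scale",
)


def measurement_feasible(
    spec: PhantomSpec,
    offsets: tuple[float, ...] = (2.95, 6.0),
    n_viewpoints: int = 5,
) -> bool:
    """Cheap closed-form check that the landmark construction is defined.

    A phantom is measurable when, for every shell offset, the shell occludes
    the brim from both incision ends (E and F exist), the dangerous zone is
    non-empty, and the brim-parallel lines through (coarse) G and H reach the
    foramen rim. Used as the cohort inclusion criterion: a study subject is,
    by definition, one on which the measurements can be taken.
    """
    s = spec.scale
    try:
        aperture = make_incision(
            np.asarray(spec.incision_proximal) * s, np.asarray(spec.incision_distal) * s, n_viewpoints
        )
        truth = PhantomTruth(
            spec=spec, offsets=tuple(offsets), aperture=aperture, quantifier="intersection",
            landmarks={}, records={}, shadow_conics={},
        )
        c = np.asarray(spec.acetabulum_center) * s
        th = np.radians(spec.brim_half_angle_deg)
        brim = spec.brim_point(np.linspace(-th, th, 2001)) * s
        x_lo, x_hi = (b * s for b in spec.plate_x_bounds)
        xs = np.arange(x_lo, x_hi, 1.0)
        ys = np.arange(spec.plate_y_min * s, spec.plate_y_max * s, 1.0)
        X, Y = np.meshgrid(xs, ys, indexing="ij")
        pts = np.stack([X.ravel(), Y.ravel(), np.zeros(X.size)], axis=-1)
        pts = pts[spec.region_contains(pts[:, :2] / s)]
        canal = spec.foramen_point(np.radians(spec.canal_angle_deg)) * s
        for d in offsets:
            for v in aperture.viewpoints:
                if np.linalg.norm(v - c) <= spec.acetabulum_radius * s + d:
                    return False
            if not truth.occluded(brim, aperture.viewpoints[-1], d).any():
                return False
            if not truth.occluded(brim, aperture.viewpoints[0], d).any():
                return False
            danger = truth.dangerous(pts, d)
            if not danger.any():
                return False
            dpts = pts[danger]
            G = dpts[int(np.argmax(np.linalg.norm(dpts - canal, axis=1)))]
            H = dpts[int(np.argmax(_arc_distance(spec, dpts)))]
            _truth_record(spec, ZoneLandmarks(E=brim[0], F=brim[-1], G=G, H=H), d)
    except (PhantomSpecError, NoIntersectionError):
        return False
    return True


def generate_cohort(
    base_spec: PhantomSpec,
    n: int,
    variation: float,
    seed: int,
    max_retries: int = 50,
) -> list[PhantomSpec]:
    """Draw ``n`` feasible specs by multiplicative perturbation of the base.

    Each perturbed scalar field f becomes f * (1 + variation * z), z ~ N(0,1),
    plus an additive jitter of the cup centre with sd = variation * radius.
    Draws that are geometrically infeasible or whose landmark construction is
    undefined (see :func:`measurement_feasible`) are retried up to
    ``max_retries`` times per subject.
    """
    if n < 1:
        raise CohortError("cohort size must be >= 1")
    if variation < 0:
        raise CohortError("variation must be non-negative")
    rng = np.random.default_rng(seed)
    specs: list[PhantomSpec] = []
    for i in range(n):
        for _ in range(max_retries):
            changes = {
                f: getattr(base_spec, f) * (1.0 + variation * rng.normal())
                for f in _PERTURBED_FIELDS
            }
            centre = np.asarray(base_spec.acetabulum_center) + variation * base_spec.acetabulum_radius * rng.normal(size=3)
            changes["acetabulum_center"] = tuple(centre)
            changes["random_seed"] = int(rng.integers(0, 2**31 - 1))
            candidate = dataclasses.replace(base_spec, **changes)
            try:
                validate_spec(candidate)
            except PhantomSpecError:
                continue
            if not measurement_feasible(candidate):
                continue
            specs.append(candidate)
            break
        else:
            raise CohortError(
                f"no feasible phantom after {max_retries} draws for subject {i} "
                f"(variation {variation} too large?)"
            )
    return specs
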