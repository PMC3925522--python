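"""Auxiliary landmark construction and distance measurement.

From the zone landmarks E, F, G, H the clinical distances are measured
against two constant intraoperative references — the pelvic brim and the
obturator foramen:

* K — foot of the perpendicular from the obturator foramen's top point to
  the brim; EK and FK locate the dangerous zone along the brim.
* M, P — feet of the perpendiculars from G and H to the brim; GM and HP are
  the depths of the dangerous zone below the brim.
* N, Q — intersections of the brim-parallel lines through G and H with the
  foramen rim; GN and HQ are the widths of the dangerous zone from the
  obturator canal.

"Perpendicular / parallel to the pelvic brim" is well defined only in a
working plane: all constructions are carried out in the least-squares plane
of the quadrilateral region, using the local brim tangent at the nearest
brim point. Distances are straight-line (segment) lengths reported in cm,
matching how they would be read off in a CAD environment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _geometry as geom
from .errors import CohortError, FrameError, NoIntersectionError
from .zones import ZoneLandmarks

MEASUREMENTS = ("EK", "FK", "GM", "GN", "HP", "HQ")

MM_PER_CM = 10.0


@dataclass(frozen=True)
class ReferenceFrame:
    """Best-fit plane of the quadrilateral region plus an in-plane basis.

    ``u`` is aligned with the brim's principal direction, ``v = normal x u``;
    2D coordinates are (p - origin) . (u, v).
    """

    origin: np.ndarray
    normal: np.ndarray
    u: np.ndarray
    v: np.ndarray

    @property
    def brim_tangent(self) -> np.ndarray:
        return self.u

    def to_plane(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float)) - self.origin
        return np.stack([pts @ self.u, pts @ self.v], axis=-1)

    def to_world(self, points2d: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points2d, dtype=float))
        return self.origin + p[:, :1] * self.u + p[:, 1:2] * self.v


def fit_reference_frame(region_points: np.ndarray, brim: np.ndarray) -> ReferenceFrame:
    """Least-squares plane through the region; in-plane x-axis along the
    principal direction of the projected brim."""
    pts = np.atleast_2d(np.asarray(region_points, dtype=float))
    if len(pts) < 3:
        raise FrameError("need at least 3 region points to fit a plane")
    origin, normal = geom.fit_plane(pts)
    # Arbitrary in-plane axes, then rotate so u follows the brim.
    a = np.array([1.0, 0.0, 0.0]) if abs(normal[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u0 = np.cross(normal, a)
    u0 /= np.linalg.norm(u0)
    v0 = np.cross(normal, u0)
    brim_pts = np.atleast_2d(np.asarray(brim, dtype=float)) - origin
    brim2 = np.stack([brim_pts @ u0, brim_pts @ v0], axis=-1)
    d2 = geom.principal_direction_2d(brim2)
    u = d2[0] * u0 + d2[1] * v0
    u /= np.linalg.norm(u)
    v = np.cross(normal, u)
    return ReferenceFrame(origin=origin, normal=normal, u=u, v=v)


def _local_tangent_2d(p2: np.ndarray, poly2: np.ndarray) -> np.ndarray:
    """Unit tangent of a 2D polyline at the vertex nearest to ``p2``
    (central difference; one-sided at the ends)."""
    d = np.linalg.norm(poly2 - p2, axis=1)
    i = int(np.argmin(d))
    j0 = max(i - 1, 0)
    j1 = min(i + 1, len(poly2) - 1)
    t = poly2[j1] - poly2[j0]
    n = np.linalg.norm(t)
    if n < 1e-12:
        raise FrameError("degenerate brim polyline (repeated points)")
    return t / n


def foot_of_perpendicular(
    point: np.ndarray,
    target_polyline: np.ndarray,
    frame: ReferenceFrame,
) -> np.ndarray:
    """Intersection of the brim-perpendicular line through ``point`` with the
    polyline, evaluated in the frame plane.

    The perpendicular direction is normal to the polyline's local tangent at
    the point's nearest polyline vertex; of the line's intersections with the
    polyline the nearest to the point is returned. If the perpendicular
    misses every segment, the nearest-point projection is used instead.
    """
    poly = np.asarray(target_polyline, dtype=float)
    if len(poly) < 2:
        raise ValueError("polyline needs at least 2 points")
    p2 = frame.to_plane(point)[0]
    poly2 = frame.to_plane(poly)
    tangent = _local_tangent_2d(p2, poly2)
    perp = np.array([-tangent[1], tangent[0]])
    hits = geom.line_polyline_intersections_2d(p2, perp, poly2)
    if len(hits):
        foot2 = hits[int(np.argmin(np.linalg.norm(hits - p2, axis=1)))]
    else:
        foot2 = geom.nearest_point_on_polyline_2d(p2, poly2)
    return frame.to_world(foot2)[0]


def line_parallel_intersection(
    point: np.ndarray,
    brim_tangent_2d: np.ndarray,
    target_polyline: np.ndarray,
    frame: ReferenceFrame,
) -> np.ndarray:
    """Nearest intersection of the brim-parallel line through ``point`` with
    a target polyline (e.g. the obturator foramen rim), in the frame plane."""
    poly2 = frame.to_plane(np.asarray(target_polyline, dtype=float))
    p2 = frame.to_plane(point)[0]
    hits = geom.line_polyline_intersections_2d(p2, brim_tangent_2d, poly2)
    if not len(hits):
        raise NoIntersectionError("brim-parallel line misses the target polyline")
    best = hits[int(np.argmin(np.linalg.norm(hits - p2, axis=1)))]
    return frame.to_world(best)[0]


@dataclass
class MeasurementRecord:
    """The six clinical distances for one subject and one shell offset."""

    subject_id: str
    offset_d: float  # mm
    EK: float
    FK: float
    GM: float
    GN: float
    HP: float
    HQ: float
    aux_points: dict[str, list[float]] = field(default_factory=dict, repr=False)

    def distances_cm(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in MEASUREMENTS}


def measure_record(
    landmarks: ZoneLandmarks,
    brim: np.ndarray,
    foramen_rim: np.ndarray,
    foramen_top: np.ndarray,
    frame: ReferenceFrame,
    subject_id: str = "subject",
    offset_d: float = float("nan"),
) -> MeasurementRecord:
    """Construct K, M, N, P, Q and measure the six distances (cm).

    K: perpendicular foot of the foramen top point on the brim. M, P:
    perpendicular feet of G and H on the brim. N, Q: brim-parallel
    intersections from G and H with the foramen rim.
    """
    brim = np.asarray(brim, dtype=float)
    rim = np.asarray(foramen_rim, dtype=float)
    brim2 = frame.to_plane(brim)

    def _measure(a: np.ndarray, b: np.ndarray) -> float:
        pa = frame.to_world(frame.to_plane(a))[0]
        return float(np.linalg.norm(pa - b)) / MM_PER_CM

    try:
        K = foot_of_perpendicular(foramen_top, brim, frame)
    except Exception as exc:
        raise type(exc)(f"constructing K: {exc}") from exc
    try:
        M = foot_of_perpendicular(landmarks.G, brim, frame)
        tangent_G = _local_tangent_2d(frame.to_plane(landmarks.G)[0], brim2)
        N = line_parallel_intersection(landmarks.G, tangent_G, rim, frame)
    except Exception as exc:
        raise type(exc)(f"constructing M/N from G: {exc}") from exc
    try:
        P = foot_of_perpendicular(landmarks.H, brim, frame)
        tangent_H = _local_tangent_2d(frame.to_plane(landmarks.H)[0], brim2)
        Q = line_parallel_intersection(landmarks.H, tangent_H, rim, frame)
    except Exception as exc:
        raise type(exc)(f"constructing P/Q from H: {exc}") from exc

    aux = {name: [float(x) for x in pt] for name, pt in
           (("K", K), ("M", M), ("N", N), ("P", P), ("Q", Q))}
    return MeasurementRecord(
        subject_id=subject_id,
        offset_d=float(offset_d),
        EK=_measure(landmarks.E, K),
        FK=_measure(landmarks.F, K),
        GM=_measure(landmarks.G, M),
        GN=_measure(landmarks.G, N),
        HP=_measure(landmarks.H, P),
        HQ=_measure(landmarks.H, Q),
        aux_points=aux,
    )


@dataclass
class CohortSummary:
    """Mean / min / max of each distance per shell offset over a cohort."""

    table: pd.DataFrame  # MultiIndex columns (measurement, stat), index offset_d
    n: dict[float, int]

    def formatted(self) -> pd.DataFrame:
        """Cells formatted "mean (min-max)" with 2 decimals, cm."""
        rows = {}
        for offset in self.table.index:
            row = {}
            for m in MEASUREMENTS:
                mean = self.table.loc[offset, (m, "mean")]
                lo = self.table.loc[offset, (m, "min")]
                hi = self.table.loc[offset, (m, "max")]
                row[m] = f"{mean:.2f} ({lo:.2f}–{hi:.2f})"
            rows[f"{offset:g} mm"] = row
        return pd.DataFrame(rows).T


def aggregate_cohort(records: list[MeasurementRecord]) -> CohortSummary:
    """Aggregate per-subject records into a per-offset mean (min-max) table."""
    if not records:
        raise CohortError("no measurement records to aggregate")
    df = pd.DataFrame(
        [{"offset_d": r.offset_d, **r.distances_cm()} for r in records]
    )
    grouped = df.groupby("offset_d").agg({m: ["mean", "min", "max"] for m in MEASUREMENTS})
    n = df.groupby("offset_d").size().to_dict()
    return CohortSummary(table=grouped, n={float(k): int(v) for k, v in n.items()})
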