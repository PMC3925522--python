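"""Triangle-mesh data model, file I/O and geometric queries.

Meshes are surface triangulations in millimetre coordinates. File handling
(STL binary/ASCII auto-detection, PLY, OBJ) is delegated to :mod:`trimesh`;
ray casting and point-surface distance use the package's own exact kernels in
:mod:`quadzone._geometry` so that every occlusion result can be checked
against a brute-force per-triangle oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh

from . import _geometry as geom
from .errors import DegenerateInputError, MeshFormatError

#: Vertices closer than this are welded on load (STL stores facets
#: independently, so welding is required before manifold queries).
WELD_TOL_MM = 1e-6

#: Hits closer than this to a ray origin are discarded (self-intersection
#: guard at entry points lying exactly on a surface).
RAY_EPS_MM = geom.RAY_EPS_MM

_SUPPORTED = {"stl", "ply", "obj"}


@dataclass
class TriangleMesh:
    """A validated triangle surface mesh.

    Parameters
    ----------
    vertices : (V, 3) float array, mm
    faces : (F, 3) int array of vertex indices
    name : free-text label carried through exports
    """

    vertices: np.ndarray
    faces: np.ndarray
    name: str = ""
    _tm: trimesh.Trimesh | None = field(default=None, repr=False, compare=False)
    _grid: tuple | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.intp).reshape(-1, 3)
        if len(self.vertices) == 0 or len(self.faces) == 0:
            raise DegenerateInputError(f"mesh {self.name!r} is empty")
        if not np.isfinite(self.vertices).all():
            raise DegenerateInputError(f"mesh {self.name!r} has non-finite coordinates")
        if self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
            raise DegenerateInputError(f"mesh {self.name!r} has out-of-range face indices")

    # -- derived views ----------------------------------------------------

    @property
    def triangles(self) -> np.ndarray:
        """(F, 3, 3) triangle corner array."""
        return self.vertices[self.faces]

    @property
    def is_watertight(self) -> bool:
        return bool(self.as_trimesh().is_watertight)

    @property
    def median_edge_length(self) -> float:
        tm = self.as_trimesh()
        return float(np.median(tm.edges_unique_length))

    def triangle_grid(self) -> tuple:
        """Lazily built uniform-grid broadphase for segment queries."""
        if self._grid is None:
            self._grid = geom.build_triangle_grid(self.triangles)
        return self._grid

    def as_trimesh(self) -> trimesh.Trimesh:
        if self._tm is None:
            self._tm = trimesh.Trimesh(vertices=self.vertices, faces=self.faces, process=False)
        return self._tm

    def copy(self, name: str | None = None) -> "TriangleMesh":
        return TriangleMesh(self.vertices.copy(), self.faces.copy(), name or self.name)


def _validated(tm: trimesh.Trimesh, name: str) -> TriangleMesh:
    """Weld duplicate vertices, drop zero-area faces, wrap."""
    tm = trimesh.Trimesh(vertices=tm.vertices, faces=tm.faces, process=False)
    tm.merge_vertices(digits_vertex=6)  # weld tolerance 1e-6 mm
    tm.update_faces(tm.nondegenerate_faces())
    tm.remove_unreferenced_vertices()
    if len(tm.faces) == 0:
        raise DegenerateInputError(f"mesh {name!r} has no non-degenerate faces")
    return TriangleMesh(np.asarray(tm.vertices), np.asarray(tm.faces), name)


def load_mesh(path: str | Path, fmt: str | None = None) -> TriangleMesh:
    """Load a surface mesh from STL (binary or ASCII), PLY or OBJ.

    Duplicate vertices are welded within :data:`WELD_TOL_MM` and degenerate
    faces removed; the returned mesh satisfies the type invariants.
    """
    path = Path(path)
    if not path.exists():
        raise MeshFormatError(f"no such file: {path}")
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt not in _SUPPORTED:
        raise MeshFormatError(f"unsupported mesh format {fmt!r} (expected one of {sorted(_SUPPORTED)})")
    try:
        tm = trimesh.load(path, file_type=fmt, force="mesh", process=False)
    except Exception as exc:  # noqa: BLE001 - normalise parser failures
        raise MeshFormatError(f"could not parse {path} as {fmt}: {exc}") from exc
    if not isinstance(tm, trimesh.Trimesh) or len(getattr(tm, "faces", [])) == 0:
        raise DegenerateInputError(f"{path} contains no triangle geometry")
    return _validated(tm, name=path.stem)


def save_mesh(mesh: TriangleMesh, path: str | Path, zone_labels: np.ndarray | None = None) -> Path:
    """Write a mesh to STL/PLY/OBJ (format from the file suffix).

    When ``zone_labels`` is given (one integer per vertex) the mesh is written
    as PLY with a per-vertex ``zone`` property (0 = safe, 1 = relatively
    dangerous, 2 = absolutely dangerous).
    """
    path = Path(path)
    fmt = path.suffix.lstrip(".").lower()
    if fmt not in _SUPPORTED:
        raise MeshFormatError(f"unsupported export format {fmt!r}")
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    if zone_labels is not None:
        if fmt != "ply":
            raise MeshFormatError("per-vertex zone labels require PLY export")
        labels = np.asarray(zone_labels, dtype=np.int32)
        if labels.shape != (len(mesh.vertices),):
            raise DegenerateInputError("zone_labels must have one entry per vertex")
        tm.vertex_attributes["zone"] = labels
        path.write_bytes(tm.export(file_type="ply", encoding="ascii"))
    else:
        tm.export(path)
    return path


@dataclass(frozen=True)
class RayHit:
    """One ray-surface intersection: parametric distance ``t`` (mm along the
    unit direction), the hit point, and the face hit."""

    t: float
    point: np.ndarray
    face_index: int


def ray_intersections(
    mesh: TriangleMesh,
    origin: np.ndarray,
    direction: np.ndarray,
    max_t: float = np.inf,
) -> list[RayHit]:
    """All intersections of a ray with a mesh, sorted by distance.

    Hits with ``t < RAY_EPS_MM`` (at the origin) or ``t > max_t`` are
    discarded. ``direction`` need not be unit length; ``t`` is reported in mm.
    """
    direction = np.asarray(direction, dtype=float)
    norm = np.linalg.norm(direction)
    if not norm > 0:
        raise ValueError("ray direction must be non-zero")
    direction = direction / norm
    origin = np.asarray(origin, dtype=float)
    ts, fidx = geom.ray_triangle_ts(origin, direction, mesh.triangles)
    keep = (ts >= RAY_EPS_MM) & (ts <= max_t)
    ts, fidx = ts[keep], fidx[keep]
    order = np.argsort(ts)
    return [
        RayHit(t=float(ts[i]), point=origin + float(ts[i]) * direction, face_index=int(fidx[i]))
        for i in order
    ]


def distance_to_surface(mesh: TriangleMesh, points: np.ndarray, signed: bool = False) -> np.ndarray:
    """Distance from points to the mesh surface.

    Unsigned by default. With ``signed=True`` (watertight meshes only) points
    inside the enclosed volume get negative sign, determined by ray-crossing
    parity along a fixed irrational direction.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    d = geom.point_triangle_distances(points, mesh.triangles)
    if not signed:
        return d
    if not mesh.is_watertight:
        raise DegenerateInputError("signed distance requires a watertight mesh")
    inside = points_inside(mesh, points)
    return np.where(inside, -d, d)


# Fixed direction with irrational components: generic w.r.t. mesh edges/faces.
_PARITY_DIR = np.array([0.5773502691896258, 0.6204836822995429, 0.5305981745143452])


def points_inside(mesh: TriangleMesh, points: np.ndarray) -> np.ndarray:
    """Inside/outside classification of points w.r.t. a watertight mesh by
    ray-crossing parity."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    tris = mesh.triangles
    out = np.zeros(len(points), dtype=bool)
    for i, p in enumerate(points):
        ts, _ = geom.ray_triangle_ts(p, _PARITY_DIR, tris)
        out[i] = (ts > RAY_EPS_MM).sum() % 2 == 1
    return out
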