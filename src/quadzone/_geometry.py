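"""Low-level geometric kernels shared across the pipeline.

All kernels are pure numpy, vectorised and chunked so that the occlusion
analysis (tens of thousands of sight segments against offset-shell meshes
with ~1e5 triangles) stays within a laptop-scale memory/time budget without
any optional spatial-index dependency.

Coordinates are millimetres throughout.
"""

from __future__ import annotations

import numpy as np

try:  # numba accelerates the hot segment-triangle kernel ~50x; optional.
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a soft dependency
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap

# Parametric tolerance guards: intersections closer than RAY_EPS_MM to either
# segment endpoint are ignored (self-intersection robustness at ray origins
# and at entry points lying exactly on a surface).
RAY_EPS_MM = 1e-6
# Determinant cutoff below which a ray is treated as parallel to a triangle.
_DET_EPS = 1e-12


def _as_triangles(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """(F, 3, 3) triangle corner array from a vertex/face pair."""
    return np.asarray(vertices, dtype=float)[np.asarray(faces, dtype=np.intp)]


def ray_triangle_ts(
    origin: np.ndarray,
    direction: np.ndarray,
    triangles: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Intersect one ray with many triangles (Moller-Trumbore).

    Parameters
    ----------
    origin, direction
        Ray origin and (not necessarily unit) direction, shape (3,).
    triangles
        (F, 3, 3) corner array.

    Returns
    -------
    t : (k,) parametric distances along ``direction`` (unnormalised), > 0.
    face_index : (k,) indices into ``triangles``; unsorted.
    """
    origin = np.asarray(origin, dtype=float)
    direction = np.asarray(direction, dtype=float)
    v0 = triangles[:, 0]
    e1 = triangles[:, 1] - v0
    e2 = triangles[:, 2] - v0
    pvec = np.cross(direction, e2)
    det = np.einsum("ij,ij->i", e1, pvec)
    ok = np.abs(det) > _DET_EPS
    inv = np.where(ok, det, 1.0)
    tvec = origin - v0
    u = np.einsum("ij,ij->i", tvec, pvec) / inv
    qvec = np.cross(tvec, e1)
    v = direction @ qvec.T / inv
    t = np.einsum("ij,ij->i", e2, qvec) / inv
    hit = ok & (u >= -1e-12) & (v >= -1e-12) & (u + v <= 1 + 1e-12) & (t > 0)
    return t[hit], np.nonzero(hit)[0]


def segments_blocked(
    viewpoint: np.ndarray,
    targets: np.ndarray,
    triangles: np.ndarray,
    *,
    eps_mm: float = RAY_EPS_MM,
    seg_chunk: int = 512,
    tri_chunk: int = 8192,
    closed_occluder: bool = False,
    grid: tuple | None = None,
) -> np.ndarray:
    """True for each target whose OPEN segment to ``viewpoint`` crosses a mesh.

    The test is exact per triangle (Moller-Trumbore with the parametric hit
    restricted to ``(eps_mm, L - eps_mm)`` along the segment of length L);
    chunking plus a bounding-sphere pre-cull keep it fast for large meshes.

    ``closed_occluder=True`` additionally culls back-facing triangles, which
    is exact for consistently outward-wound closed surfaces: any segment
    entering the enclosed volume crosses a front face.
    """
    viewpoint = np.asarray(viewpoint, dtype=float)
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    n = len(targets)
    blocked = np.zeros(n, dtype=bool)
    if len(triangles) == 0 or n == 0:
        return blocked
    if closed_occluder and grid is None:
        e1f = triangles[:, 1] - triangles[:, 0]
        e2f = triangles[:, 2] - triangles[:, 0]
        nrm = np.cross(e1f, e2f)
        toward = triangles.mean(axis=1) - viewpoint
        triangles = triangles[np.einsum("ij,ij->i", nrm, toward) < 0]
        if len(triangles) == 0:
            return blocked

    # Bounding-sphere pre-cull: a segment whose supporting line stays farther
    # from the mesh's bounding-sphere centre than its radius cannot hit.
    lo = triangles.reshape(-1, 3).min(axis=0)
    hi = triangles.reshape(-1, 3).max(axis=0)
    centre = 0.5 * (lo + hi)
    radius = 0.5 * float(np.linalg.norm(hi - lo)) + 1e-9
    d = targets - viewpoint
    seg_len2 = np.einsum("ij,ij->i", d, d)
    w = centre - viewpoint
    s = np.clip(np.einsum("ij,j->i", d, w) / np.maximum(seg_len2, 1e-300), 0.0, 1.0)
    closest = viewpoint + s[:, None] * d
    candidate = np.linalg.norm(closest - centre, axis=1) <= radius
    idx_all = np.nonzero(candidate)[0]
    if idx_all.size == 0:
        return blocked

    if _HAVE_NUMBA:
        lens = np.sqrt(seg_len2[idx_all])
        if len(triangles) >= 4096 and grid is not None:
            cell, ncell, g_lo, counts, starts, items = grid
            blocked[idx_all] = _blocked_kernel_grid(
                viewpoint, targets[idx_all], np.ascontiguousarray(triangles), lens, eps_mm,
                cell, ncell, g_lo, counts, starts, items,
            )
        else:
            blocked[idx_all] = _blocked_kernel(
                viewpoint, targets[idx_all], np.ascontiguousarray(triangles), lens, eps_mm
            )
        return blocked

    v0 = triangles[:, 0]
    e1 = triangles[:, 1] - v0
    e2 = triangles[:, 2] - v0

    for s0 in range(0, idx_all.size, seg_chunk):
        idx = idx_all[s0 : s0 + seg_chunk]
        dirs = d[idx]                                   # (S, 3)
        lens = np.sqrt(seg_len2[idx])
        t_lo = eps_mm / np.maximum(lens, 1e-300)
        t_hi = 1.0 - t_lo
        hit = np.zeros(len(idx), dtype=bool)
        tvec_full = viewpoint - v0                      # (F, 3), constant
        for f0 in range(0, len(triangles), tri_chunk):
            live = ~hit
            if not live.any():
                break
            dl = dirs[live]
            e2c = e2[f0 : f0 + tri_chunk]
            e1c = e1[f0 : f0 + tri_chunk]
            tv = tvec_full[f0 : f0 + tri_chunk]
            pvec = np.cross(dl[:, None, :], e2c[None, :, :])   # (S, F, 3)
            det = np.einsum("fj,sfj->sf", e1c, pvec)
            ok = np.abs(det) > _DET_EPS
            inv = np.where(ok, det, 1.0)
            u = np.einsum("fj,sfj->sf", tv, pvec) / inv
            qvec = np.cross(tv[None, :, :], e1c[None, :, :])   # (1, F, 3)
            v = np.einsum("sj,sfj->sf", dl, np.broadcast_to(qvec, pvec.shape)) / inv
            t = np.einsum("fj,fj->f", e2c, qvec[0])[None, :] / inv
            lo_b = t_lo[live][:, None]
            hi_b = t_hi[live][:, None]
            h = ok & (u >= 0) & (v >= 0) & (u + v <= 1) & (t > lo_b) & (t < hi_b)
            hit[live] |= h.any(axis=1)
        blocked[idx] = hit
    return blocked


def build_triangle_grid(triangles: np.ndarray, target_per_cell: float = 12.0):
    """Uniform-grid broadphase over a triangle soup.

    Bins triangles into cells overlapped by their AABBs (CSR layout); the
    segment kernel walks cells with a 3D DDA and only tests local triangles.
    Returns the tuple consumed by :func:`segments_blocked`'s ``grid`` arg.
    """
    lo = triangles.reshape(-1, 3).min(axis=0) - 1e-6
    hi = triangles.reshape(-1, 3).max(axis=0) + 1e-6
    extent = hi - lo
    n_tri = len(triangles)
    cell = float(max((extent.prod() * target_per_cell / max(n_tri, 1)) ** (1 / 3), extent.max() / 256))
    ncell = np.maximum((extent / cell).astype(np.int64) + 1, 1)

    tlo = triangles.min(axis=1)
    thi = triangles.max(axis=1)
    ilo = np.clip(((tlo - lo) / cell).astype(np.int64), 0, ncell - 1)
    ihi = np.clip(((thi - lo) / cell).astype(np.int64), 0, ncell - 1)

    spans = (ihi - ilo + 1).prod(axis=1)
    total = int(spans.sum())
    tri_ids = np.empty(total, dtype=np.int64)
    cell_ids = np.empty(total, dtype=np.int64)
    pos = 0
    stride = np.array([ncell[1] * ncell[2], ncell[2], 1], dtype=np.int64)
    for t in range(n_tri):
        xs = np.arange(ilo[t, 0], ihi[t, 0] + 1)
        ys = np.arange(ilo[t, 1], ihi[t, 1] + 1)
        zs = np.arange(ilo[t, 2], ihi[t, 2] + 1)
        ids = (
            xs[:, None, None] * stride[0]
            + ys[None, :, None] * stride[1]
            + zs[None, None, :]
        ).ravel()
        tri_ids[pos : pos + len(ids)] = t
        cell_ids[pos : pos + len(ids)] = ids
        pos += len(ids)

    order = np.argsort(cell_ids, kind="stable")
    cell_sorted = cell_ids[order]
    items = tri_ids[order]
    n_cells = int(ncell.prod())
    counts = np.bincount(cell_sorted, minlength=n_cells).astype(np.int64)
    starts = np.concatenate([[0], np.cumsum(counts)[:-1]]).astype(np.int64)
    return (cell, ncell.astype(np.int64), lo, counts, starts, items)


@njit(cache=True)
def _blocked_kernel_grid(vp, targets, tris, lens, eps_mm, cell, ncell, g_lo, counts, starts, items):  # pragma: no cover - numba
    n = targets.shape[0]
    out = np.zeros(n, dtype=np.bool_)
    sx = ncell[1] * ncell[2]
    sy = ncell[2]
    for i in range(n):
        ox, oy, oz = vp[0], vp[1], vp[2]
        dx = targets[i, 0] - ox
        dy = targets[i, 1] - oy
        dz = targets[i, 2] - oz
        t_lo = eps_mm / lens[i]
        t_hi = 1.0 - t_lo
        # Clip the segment (t in [0,1]) to the grid AABB.
        tmin, tmax = 0.0, 1.0
        good = True
        for k in range(3):
            o = vp[k]
            d = targets[i, k] - o
            b0 = g_lo[k]
            b1 = g_lo[k] + cell * ncell[k]
            if abs(d) < 1e-300:
                if o < b0 or o > b1:
                    good = False
                    break
            else:
                ta = (b0 - o) / d
                tb = (b1 - o) / d
                if ta > tb:
                    ta, tb = tb, ta
                if ta > tmin:
                    tmin = ta
                if tb < tmax:
                    tmax = tb
        if not good or tmin > tmax:
            continue
        # DDA setup at entry point.
        px = ox + tmin * dx
        py = oy + tmin * dy
        pz = oz + tmin * dz
        cx = int((px - g_lo[0]) / cell)
        cy = int((py - g_lo[1]) / cell)
        cz = int((pz - g_lo[2]) / cell)
        if cx < 0:
            cx = 0
        if cy < 0:
            cy = 0
        if cz < 0:
            cz = 0
        if cx >= ncell[0]:
            cx = ncell[0] - 1
        if cy >= ncell[1]:
            cy = ncell[1] - 1
        if cz >= ncell[2]:
            cz = ncell[2] - 1
        stepx = 1 if dx > 0 else -1
        stepy = 1 if dy > 0 else -1
        stepz = 1 if dz > 0 else -1
        big = 1e300
        tdx = abs(cell / dx) if dx != 0 else big
        tdy = abs(cell / dy) if dy != 0 else big
        tdz = abs(cell / dz) if dz != 0 else big
        nextx = (g_lo[0] + (cx + (stepx > 0)) * cell - ox) / dx if dx != 0 else big
        nexty = (g_lo[1] + (cy + (stepy > 0)) * cell - oy) / dy if dy != 0 else big
        nextz = (g_lo[2] + (cz + (stepz > 0)) * cell - oz) / dz if dz != 0 else big
        hit = False
        while True:
            base = cx * sx + cy * sy + cz
            s0 = starts[base]
            for jj in range(counts[base]):
                f = items[s0 + jj]
                ax, ay, az = tris[f, 0, 0], tris[f, 0, 1], tris[f, 0, 2]
                e1x = tris[f, 1, 0] - ax
                e1y = tris[f, 1, 1] - ay
                e1z = tris[f, 1, 2] - az
                e2x = tris[f, 2, 0] - ax
                e2y = tris[f, 2, 1] - ay
                e2z = tris[f, 2, 2] - az
                qpx = dy * e2z - dz * e2y
                qpy = dz * e2x - dx * e2z
                qpz = dx * e2y - dy * e2x
                det = e1x * qpx + e1y * qpy + e1z * qpz
                if -1e-12 < det < 1e-12:
                    continue
                inv = 1.0 / det
                tx = ox - ax
                ty = oy - ay
                tz = oz - az
                u = (tx * qpx + ty * qpy + tz * qpz) * inv
                if u < 0.0 or u > 1.0:
                    continue
                qx = ty * e1z - tz * e1y
                qy = tz * e1x - tx * e1z
                qz = tx * e1y - ty * e1x
                v = (dx * qx + dy * qy + dz * qz) * inv
                if v < 0.0 or u + v > 1.0:
                    continue
                t = (e2x * qx + e2y * qy + e2z * qz) * inv
                if t_lo < t < t_hi:
                    hit = True
                    break
            if hit:
                break
            # advance to the next cell along the segment
            if nextx <= nexty and nextx <= nextz:
                if nextx > tmax or nextx > 1.0:
                    break
                cx += stepx
                if cx < 0 or cx >= ncell[0]:
                    break
                nextx += tdx
            elif nexty <= nextz:
                if nexty > tmax or nexty > 1.0:
                    break
                cy += stepy
                if cy < 0 or cy >= ncell[1]:
                    break
                nexty += tdy
            else:
                if nextz > tmax or nextz > 1.0:
                    break
                cz += stepz
                if cz < 0 or cz >= ncell[2]:
                    break
                nextz += tdz
        out[i] = hit
    return out


@njit(cache=True)
def _blocked_kernel(vp, targets, tris, lens, eps_mm):  # pragma: no cover - numba
    n = targets.shape[0]
    out = np.zeros(n, dtype=np.bool_)
    F = tris.shape[0]
    for i in range(n):
        dx = targets[i, 0] - vp[0]
        dy = targets[i, 1] - vp[1]
        dz = targets[i, 2] - vp[2]
        t_lo = eps_mm / lens[i]
        t_hi = 1.0 - t_lo
        for f in range(F):
            ax, ay, az = tris[f, 0, 0], tris[f, 0, 1], tris[f, 0, 2]
            e1x = tris[f, 1, 0] - ax
            e1y = tris[f, 1, 1] - ay
            e1z = tris[f, 1, 2] - az
            e2x = tris[f, 2, 0] - ax
            e2y = tris[f, 2, 1] - ay
            e2z = tris[f, 2, 2] - az
            px = dy * e2z - dz * e2y
            py = dz * e2x - dx * e2z
            pz = dx * e2y - dy * e2x
            det = e1x * px + e1y * py + e1z * pz
            if -1e-12 < det < 1e-12:
                continue
            inv = 1.0 / det
            tx = vp[0] - ax
            ty = vp[1] - ay
            tz = vp[2] - az
            u = (tx * px + ty * py + tz * pz) * inv
            if u < 0.0 or u > 1.0:
                continue
            qx = ty * e1z - tz * e1y
            qy = tz * e1x - tx * e1z
            qz = tx * e1y - ty * e1x
            v = (dx * qx + dy * qy + dz * qz) * inv
            if v < 0.0 or u + v > 1.0:
                continue
            t = (e2x * qx + e2y * qy + e2z * qz) * inv
            if t_lo < t < t_hi:
                out[i] = True
                break
    return out


def point_triangle_distances(
    points: np.ndarray,
    triangles: np.ndarray,
    *,
    pt_chunk: int = 256,
    tri_chunk: int = 4096,
) -> np.ndarray:
    """Unsigned distance from each point to the nearest triangle.

    Closest-point-on-triangle via the standard barycentric region test
    (Ericson, *Real-Time Collision Detection*), vectorised over point and
    triangle chunks; exact up to floating point.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    out = np.full(len(points), np.inf)
    a = triangles[:, 0]
    b = triangles[:, 1]
    c = triangles[:, 2]
    for p0 in range(0, len(points), pt_chunk):
        p = points[p0 : p0 + pt_chunk]
        best = np.full(len(p), np.inf)
        for f0 in range(0, len(triangles), tri_chunk):
            d2 = _point_tri_d2(p, a[f0 : f0 + tri_chunk], b[f0 : f0 + tri_chunk], c[f0 : f0 + tri_chunk])
            best = np.minimum(best, d2.min(axis=1))
        out[p0 : p0 + pt_chunk] = np.sqrt(best)
    return out


def _point_tri_d2(p: np.ndarray, a: np.ndarray, b: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Squared distances, shape (P, F), from points (P,3) to triangles."""
    ab = b - a
    ac = c - a
    ap = p[:, None, :] - a[None, :, :]                  # (P, F, 3)
    d1 = np.einsum("fj,pfj->pf", ab, ap)
    d2 = np.einsum("fj,pfj->pf", ac, ap)
    bp = p[:, None, :] - b[None, :, :]
    d3 = np.einsum("fj,pfj->pf", ab, bp)
    d4 = np.einsum("fj,pfj->pf", ac, bp)
    cp = p[:, None, :] - c[None, :, :]
    d5 = np.einsum("fj,pfj->pf", ab, cp)
    d6 = np.einsum("fj,pfj->pf", ac, cp)

    va = d3 * d6 - d5 * d4
    vb = d5 * d2 - d1 * d6
    vc = d1 * d4 - d3 * d2
    denom = va + vb + vc
    denom = np.where(np.abs(denom) < 1e-300, 1.0, denom)
    v = vb / denom
    w = vc / denom

    # Interior candidate
    closest = a[None] + v[..., None] * ab[None] + w[..., None] * ac[None]

    # Vertex regions
    cond_a = (d1 <= 0) & (d2 <= 0)
    cond_b = (d3 >= 0) & (d4 <= d3)
    cond_c = (d6 >= 0) & (d5 <= d6)
    # Edge regions
    vab = d1 * d4 - d3 * d2
    cond_ab = (~cond_a) & (~cond_b) & (vab <= 0) & (d1 >= 0) & (d3 <= 0)
    t_ab = np.where(cond_ab, d1 / np.where(d1 - d3 == 0, 1.0, d1 - d3), 0.0)
    vac = d5 * d2 - d1 * d6
    cond_ac = (~cond_a) & (~cond_c) & (vac <= 0) & (d2 >= 0) & (d6 <= 0)
    t_ac = np.where(cond_ac, d2 / np.where(d2 - d6 == 0, 1.0, d2 - d6), 0.0)
    vbc = d3 * d6 - d5 * d4
    cond_bc = (~cond_b) & (~cond_c) & (vbc <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    den_bc = (d4 - d3) + (d5 - d6)
    t_bc = np.where(cond_bc, (d4 - d3) / np.where(den_bc == 0, 1.0, den_bc), 0.0)

    closest = np.where(cond_bc[..., None], b[None] + t_bc[..., None] * (c - b)[None], closest)
    closest = np.where(cond_ac[..., None], a[None] + t_ac[..., None] * ac[None], closest)
    closest = np.where(cond_ab[..., None], a[None] + t_ab[..., None] * ab[None], closest)
    closest = np.where(cond_c[..., None], c[None, :, :] * np.ones_like(closest), closest)
    closest = np.where(cond_b[..., None], b[None, :, :] * np.ones_like(closest), closest)
    closest = np.where(cond_a[..., None], a[None, :, :] * np.ones_like(closest), closest)

    diff = p[:, None, :] - closest
    return np.einsum("pfj,pfj->pf", diff, diff)


def fit_plane(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares plane through a point cloud.

    Returns (centroid, unit normal). The normal is the singular vector of the
    smallest singular value; its sign is canonicalised so the largest-magnitude
    component is positive (deterministic across platforms).
    """
    pts = np.asarray(points, dtype=float)
    centroid = pts.mean(axis=0)
    u, s, vt = np.linalg.svd(pts - centroid, full_matrices=False)
    normal = vt[-1]
    k = int(np.argmax(np.abs(normal)))
    if normal[k] < 0:
        normal = -normal
    # Degeneracy: collinear clouds have two ~zero singular values.
    if s.size < 3 or s[1] <= 1e-9 * max(s[0], 1.0):
        from .errors import FrameError

        raise FrameError("points are collinear or degenerate; no unique plane")
    return centroid, normal


def principal_direction_2d(points2d: np.ndarray) -> np.ndarray:
    """Unit principal axis of a 2D point cloud (sign canonicalised)."""
    pts = np.asarray(points2d, dtype=float)
    centred = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    d = vt[0]
    k = int(np.argmax(np.abs(d)))
    if d[k] < 0:
        d = -d
    return d / np.linalg.norm(d)


def line_polyline_intersections_2d(
    point: np.ndarray, direction: np.ndarray, polyline: np.ndarray
) -> np.ndarray:
    """All intersections of an infinite 2D line with a 2D polyline.

    Returns an (k, 2) array of intersection points (may be empty).
    """
    p = np.asarray(point, dtype=float)
    u = np.asarray(direction, dtype=float)
    u = u / np.linalg.norm(u)
    a = np.asarray(polyline, dtype=float)[:-1]
    b = np.asarray(polyline, dtype=float)[1:]
    e = b - a
    # Solve p + s*u = a + t*e  for each segment; cross-product form.
    denom = u[0] * e[:, 1] - u[1] * e[:, 0]
    ok = np.abs(denom) > 1e-12
    w = a - p
    s = np.where(ok, (w[:, 0] * e[:, 1] - w[:, 1] * e[:, 0]) / np.where(ok, denom, 1.0), np.nan)
    t = np.where(ok, (w[:, 0] * u[1] - w[:, 1] * u[0]) / -np.where(ok, denom, 1.0), np.nan)
    hit = ok & (t >= -1e-9) & (t <= 1 + 1e-9)
    return p + s[hit, None] * u


def nearest_point_on_polyline_2d(point: np.ndarray, polyline: np.ndarray) -> np.ndarray:
    """Closest point on a 2D polyline to ``point`` (exact per segment)."""
    p = np.asarray(point, dtype=float)
    a = np.asarray(polyline, dtype=float)[:-1]
    b = np.asarray(polyline, dtype=float)[1:]
    e = b - a
    ee = np.einsum("ij,ij->i", e, e)
    t = np.clip(np.einsum("ij,ij->i", p - a, e) / np.maximum(ee, 1e-300), 0.0, 1.0)
    cand = a + t[:, None] * e
    d2 = np.einsum("ij,ij->i", cand - p, cand - p)
    return cand[int(np.argmin(d2))]


def polyline_distances(points: np.ndarray, polyline: np.ndarray) -> np.ndarray:
    """Distance from each point (N, k) to a polyline ((M, k) vertices), exact
    per segment; works in 2D or 3D."""
    p = np.atleast_2d(np.asarray(points, dtype=float))
    poly = np.asarray(polyline, dtype=float)
    a = poly[:-1]
    e = poly[1:] - a
    ee = np.einsum("ij,ij->i", e, e)
    out = np.full(len(p), np.inf)
    for s0 in range(0, len(a), 4096):
        ac = a[s0 : s0 + 4096]
        ec = e[s0 : s0 + 4096]
        eec = np.maximum(ee[s0 : s0 + 4096], 1e-300)
        w = p[:, None, :] - ac[None, :, :]
        t = np.clip(np.einsum("psj,sj->ps", w, ec) / eec, 0.0, 1.0)
        diff = w - t[..., None] * ec[None, :, :]
        d2 = np.einsum("psj,psj->ps", diff, diff)
        out = np.minimum(out, np.sqrt(d2.min(axis=1)))
    return out


def densify_polyline(polyline: np.ndarray, spacing: float) -> np.ndarray:
    """Resample a polyline so consecutive samples are at most ``spacing`` apart.

    Original vertices are retained; each segment is subdivided uniformly.
    """
    pts = np.asarray(polyline, dtype=float)
    if len(pts) < 2:
        return pts.copy()
    out = [pts[:1]]
    for a, b in zip(pts[:-1], pts[1:]):
        seg = np.linalg.norm(b - a)
        n = max(1, int(np.ceil(seg / spacing)))
        ts = np.linspace(0.0, 1.0, n + 1)[1:]
        out.append(a + ts[:, None] * (b - a))
    return np.vstack(out)
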