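"""Exact point-to-surface distance and point-in-mesh queries.

Small, vectorized geometric kernels used by the Hausdorff metric, surface
ICP correspondence and the mesh interpenetration checks.  Distances are
exact point-to-triangle (Ericson's closest-point-on-triangle), accelerated
by a rigorous triangle-centroid prune: a triangle can only beat the current
upper bound ``d_u`` (distance to the nearest vertex) if its centroid lies
within ``d_u + r_t`` of the query point, where ``r_t`` is the triangle's
circumscribing vertex radius.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

__all__ = ["closest_on_triangles", "closest_on_surface", "points_in_mesh"]


def _closest_point_on_triangle(p: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Closest points on matched triangles; ``p`` (n,3), ``tri`` (n,3,3)."""
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab, ac, ap = b - a, c - a, p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    out = np.empty_like(p)
    done = np.zeros(len(p), dtype=bool)

    def settle(mask, value):
        m = mask & ~done
        out[m] = value[m]
        done[m] = True

    settle((d1 <= 0) & (d2 <= 0), a)  # vertex region A
    settle((d3 >= 0) & (d4 <= d3), b)  # vertex region B
    settle((d6 >= 0) & (d5 <= d6), c)  # vertex region C

    vc = d1 * d4 - d3 * d2
    with np.errstate(divide="ignore", invalid="ignore"):
        v_ab = np.where(d1 - d3 != 0, d1 / (d1 - d3), 0.0)
    settle((vc <= 0) & (d1 >= 0) & (d3 <= 0), a + v_ab[:, None] * ab)  # edge AB

    vb = d5 * d2 - d1 * d6
    with np.errstate(divide="ignore", invalid="ignore"):
        w_ac = np.where(d2 - d6 != 0, d2 / (d2 - d6), 0.0)
    settle((vb <= 0) & (d2 >= 0) & (d6 <= 0), a + w_ac[:, None] * ac)  # edge AC

    va = d3 * d6 - d5 * d4
    denom_bc = (d4 - d3) + (d5 - d6)
    with np.errstate(divide="ignore", invalid="ignore"):
        w_bc = np.where(denom_bc != 0, (d4 - d3) / denom_bc, 0.0)
    settle((va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0), b + w_bc[:, None] * (c - b))

    # interior
    denom = va + vb + vc
    with np.errstate(divide="ignore", invalid="ignore"):
        v = np.where(denom != 0, vb / denom, 1 / 3)
        w = np.where(denom != 0, vc / denom, 1 / 3)
    settle(np.ones(len(p), dtype=bool), a + v[:, None] * ab + w[:, None] * ac)
    return out


def closest_on_triangles(points: np.ndarray, triangles: np.ndarray):
    """Brute-force closest point over a triangle soup; (closest (n,3), dist (n,))."""
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    triangles = np.asarray(triangles, dtype=float).reshape(-1, 3, 3)
    n, t = len(points), len(triangles)
    best_d = np.full(n, np.inf)
    best_p = np.zeros((n, 3))
    chunk = max(1, int(4_000_000 // max(t, 1)))
    for s in range(0, n, chunk):
        p = points[s : s + chunk]
        m = len(p)
        pp = np.repeat(p, t, axis=0)
        tt = np.tile(triangles, (m, 1, 1))
        cp = _closest_point_on_triangle(pp, tt).reshape(m, t, 3)
        d = np.linalg.norm(cp - p[:, None, :], axis=2)
        k = np.argmin(d, axis=1)
        best_d[s : s + chunk] = d[np.arange(m), k]
        best_p[s : s + chunk] = cp[np.arange(m), k]
    return best_p, best_d


def closest_on_surface(points: np.ndarray, mesh):
    """Exact closest points on a triangulated surface, centroid-pruned.

    Returns ``(closest_points (n,3), distances (n,))``.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    tri = np.asarray(mesh.triangles, dtype=float)
    if len(tri) == 0:
        raise ValueError("mesh has no faces")
    if len(tri) <= 256:
        return closest_on_triangles(points, tri)

    centroids = tri.mean(axis=1)
    tri_radius = np.linalg.norm(tri - centroids[:, None, :], axis=2).max(axis=1)
    r_max = float(tri_radius.max())
    kd_v = cKDTree(np.asarray(mesh.vertices, dtype=float))
    kd_c = cKDTree(centroids)

    d_upper, _ = kd_v.query(points)  # nearest vertex lies on the surface
    cand = kd_c.query_ball_point(points, d_upper + r_max + 1e-12)
    pidx = np.concatenate([np.full(len(c), i) for i, c in enumerate(cand)])
    tidx = np.concatenate([np.asarray(c, dtype=int) for c in cand])
    cp = _closest_point_on_triangle(points[pidx], tri[tidx])
    d = np.linalg.norm(cp - points[pidx], axis=1)
    # reduce to per-point argmin
    order = np.lexsort((d, pidx))
    first = np.unique(pidx[order], return_index=True)[1]
    sel = order[first]
    best_p = np.empty_like(points)
    best_d = np.empty(len(points))
    best_p[pidx[sel]] = cp[sel]
    best_d[pidx[sel]] = d[sel]
    return best_p, best_d


_RAY_DIR = np.array([0.5231262154, 0.6370531418, 0.5662019875])


def points_in_mesh(mesh, points: np.ndarray, direction=None) -> np.ndarray:
    """Even-odd containment test against a watertight mesh.

    Vectorized Moeller-Trumbore crossing count along a fixed generic ray
    direction; intended for modest triangle counts (interpenetration checks
    on phantom vertebrae), cost O(points x triangles).
    """
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    tri = np.asarray(mesh.triangles, dtype=float)
    d = _RAY_DIR if direction is None else np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    e1, e2 = b - a, c - a
    h = np.cross(d, e2)
    det = np.einsum("ij,ij->i", e1, h)
    ok = np.abs(det) > 1e-12
    inv = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)

    inside = np.zeros(len(points), dtype=bool)
    t_count = len(tri)
    chunk = max(1, int(2_000_000 // max(t_count, 1)))
    for s0 in range(0, len(points), chunk):
        p = points[s0 : s0 + chunk]
        s = p[:, None, :] - a[None, :, :]
        u = np.einsum("pij,ij->pi", s, h) * inv[None, :]
        q = np.cross(s, e1[None, :, :])
        v = np.einsum("pij,j->pi", q, d) * inv[None, :]
        t = np.einsum("pij,ij->pi", q, e2) * inv[None, :]
        hit = (
            ok[None, :]
            & (u >= 0.0)
            & (v >= 0.0)
            & (u + v <= 1.0)
            & (t > 1e-9)
        )
        inside[s0 : s0 + chunk] = (hit.sum(axis=1) % 2).astype(bool)
    return inside
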