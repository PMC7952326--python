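"""Chamber-geometry analysis.

The chamber shell exported by a mapping system is a triangulated surface
with holes where valves and veins were excluded ("anatomical structures").
This module finds those free-boundary rims, closes them, and computes the
open/closed surface area, the enclosed volume (divergence theorem over
consistently oriented triangles) and interior/exterior status of catheter
points (ray-casting parity against the closed shell).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import MissingDataError, TopologyError
from .model import SurfaceMesh, UserData

__all__ = [
    "BoundaryLoop",
    "PointStatusResult",
    "get_anatomical_structures",
    "fill_holes",
    "get_area",
    "get_volume",
    "point_status",
    "closest_point_on_mesh",
]


@dataclass
class BoundaryLoop:
    """One free-boundary rim: an ordered, closed cycle of vertex indices."""

    vertex_indices: np.ndarray  # ordered cycle, first != last (implicitly closed)
    perimeter: float  # mm
    area: float  # cm^2, fan-triangulation estimate of the enclosed patch
    centroid: np.ndarray  # mm


@dataclass
class PointStatusResult:
    """Interior/exterior classification of electric points vs the closed
    chamber, with distance to the (open) surface."""

    inside: np.ndarray  # (p,) bool
    distance: np.ndarray  # (p,) mm, min distance to surface
    surface_tolerance: float  # mm, reported alongside (classification is strict)


def _mesh_of(obj) -> SurfaceMesh:
    if isinstance(obj, UserData):
        if obj.surface is None:
            raise MissingDataError("study has no surface mesh")
        return obj.surface
    if isinstance(obj, SurfaceMesh):
        return obj
    raise TypeError("expected UserData or SurfaceMesh")


def _loop_fan_geometry(mesh: SurfaceMesh, cycle: np.ndarray):
    pts = mesh.vertices[cycle]
    centroid = pts.mean(axis=0)
    nxt = np.roll(pts, -1, axis=0)
    perim = float(np.linalg.norm(nxt - pts, axis=1).sum())
    fan = 0.5 * np.linalg.norm(np.cross(pts - centroid, nxt - centroid), axis=1)
    return perim, float(fan.sum()), centroid, fan


def get_anatomical_structures(mesh_or_userdata) -> list:
    """Detect anatomical-structure rims (free-boundary loops).

    Free edges (incident to exactly one triangle) are traced into closed
    vertex cycles.  Each loop reports its perimeter (mm), an enclosed-area
    estimate from a triangle fan to the loop centroid (cm^2), and the
    centroid.  Loops are sorted by descending perimeter.
    """
    mesh = _mesh_of(mesh_or_userdata)
    edges, counts = mesh.unique_edges()
    if counts.size and counts.max() > 2:
        raise TopologyError("non-manifold edge shared by >2 triangles")
    free = edges[counts == 1]
    if len(free) == 0:
        return []
    # adjacency over boundary vertices; on a manifold-with-boundary each
    # boundary vertex has exactly two incident free edges
    adj: dict = {}
    for a, b in free:
        adj.setdefault(int(a), []).append(int(b))
        adj.setdefault(int(b), []).append(int(a))
    for v, nbrs in adj.items():
        if len(nbrs) != 2:
            raise TopologyError(
                f"boundary vertex {v} has {len(nbrs)} free edges; rims touch"
            )
    seen = set()
    loops = []
    for start in sorted(adj):
        if start in seen:
            continue
        cycle = [start]
        seen.add(start)
        prev, cur = None, start
        while True:
            a, b = adj[cur]
            nxt = a if a != prev else b
            if nxt == start:
                break
            cycle.append(nxt)
            seen.add(nxt)
            prev, cur = cur, nxt
        cyc = np.asarray(cycle, dtype=np.int64)
        perim, fan_area_mm2, centroid, _ = _loop_fan_geometry(mesh, cyc)
        loops.append(BoundaryLoop(cyc, perim, fan_area_mm2 / 100.0, centroid))
    loops.sort(key=lambda L: -L.perimeter)
    return loops


def fill_holes(mesh_or_userdata, loops=None) -> SurfaceMesh:
    """Close free-boundary loops with a fan to a new centroid vertex.

    By default every loop is closed (a chamber's valve and vein cut-outs
    all get capped); pass ``loops`` (a subset of
    :func:`get_anatomical_structures` results) to close selected rims
    only, e.g. an interior hole of an open patch while keeping its outer
    rim.  One vertex is appended per closed loop; original vertices and
    triangles are unchanged, and per-vertex fields are extended with NaN
    at the new vertices.  Idempotent on closed meshes.
    """
    mesh = _mesh_of(mesh_or_userdata)
    if loops is None:
        loops = get_anatomical_structures(mesh)
    if not loops:
        return mesh.copy()
    verts = [mesh.vertices]
    tris = [mesh.triangles]
    next_idx = mesh.n_vertices
    for L in loops:
        verts.append(L.centroid[None, :])
        cyc = L.vertex_indices
        nxt = np.roll(cyc, -1)
        fan = np.stack([cyc, nxt, np.full(len(cyc), next_idx)], axis=1)
        tris.append(fan)
        next_idx += 1
    fields = {
        k: np.concatenate([v, np.full(len(loops), np.nan)])
        for k, v in mesh.fields.items()
    }
    return SurfaceMesh(np.vstack(verts), np.vstack(tris), fields)


def get_area(mesh_or_userdata, method: str = "nofill", units: str = "cm2") -> float:
    """Chamber surface area.

    ``method='nofill'`` sums triangle areas of the open mesh (cut-outs left
    open); ``method='fill'`` closes every rim first, so fill >= nofill.
    Returned in cm^2 by default (``units='mm2'`` for raw values).
    """
    mesh = _mesh_of(mesh_or_userdata)
    if method == "nofill":
        area_mm2 = mesh.total_area()
    elif method == "fill":
        area_mm2 = fill_holes(mesh).total_area()
    else:
        raise ValueError(f"unknown area method {method!r}; use 'nofill' or 'fill'")
    if units == "cm2":
        return area_mm2 / 100.0
    if units == "mm2":
        return area_mm2
    raise ValueError(f"unknown units {units!r}")


def _orient_consistently(triangles: np.ndarray) -> np.ndarray:
    """Flip triangle windings so every shared edge is traversed in opposite
    directions by its two triangles (breadth-first propagation)."""
    m = len(triangles)
    t = triangles.copy()
    # map sorted edge -> incident triangle ids
    edge_map: dict = {}
    for ti in range(m):
        tri = t[ti]
        for k in range(3):
            e = (int(tri[k]), int(tri[(k + 1) % 3]))
            key = (min(e), max(e))
            edge_map.setdefault(key, []).append(ti)
    visited = np.zeros(m, dtype=bool)
    for seed in range(m):
        if visited[seed]:
            continue
        visited[seed] = True
        queue = [seed]
        while queue:
            ti = queue.pop()
            tri = t[ti]
            directed = {(int(tri[k]), int(tri[(k + 1) % 3])) for k in range(3)}
            for k in range(3):
                a, b = int(tri[k]), int(tri[(k + 1) % 3])
                key = (min(a, b), max(a, b))
                for tj in edge_map[key]:
                    if tj == ti:
                        continue
                    trj = t[tj]
                    dj = {(int(trj[q]), int(trj[(q + 1) % 3])) for q in range(3)}
                    same_dir = (a, b) in dj
                    if visited[tj]:
                        if same_dir:
                            raise TopologyError("surface is non-orientable")
                        continue
                    if same_dir:
                        t[tj] = trj[::-1]
                    visited[tj] = True
                    queue.append(tj)
    return t


def get_volume(mesh_or_userdata, units: str = "cm3") -> float:
    """Enclosed chamber volume by the divergence theorem.

    Holes are closed automatically (:func:`fill_holes`), triangle winding is
    made consistent by breadth-first propagation across shared edges, and
    the magnitude of the summed signed tetrahedron volumes
    ``(1/6) det[a, b, c]`` is returned — so the result is independent of
    global orientation and of any translation of the chamber.
    """
    mesh = _mesh_of(mesh_or_userdata)
    closed = fill_holes(mesh)
    tris = _orient_consistently(closed.triangles)
    v = closed.vertices
    # subtract the centroid: mathematically a no-op for a closed surface,
    # numerically it keeps the signed-tetra cancellation well conditioned
    v = v - v.mean(axis=0)
    a, b, c = v[tris[:, 0]], v[tris[:, 1]], v[tris[:, 2]]
    signed = np.einsum("ij,ij->i", a, np.cross(b, c)).sum() / 6.0
    vol_mm3 = abs(float(signed))
    if units == "cm3":
        return vol_mm3 / 1000.0
    if units == "mm3":
        return vol_mm3
    raise ValueError(f"unknown units {units!r}")


# -- ray casting & distances ---------------------------------------------


def _ray_crossings(origins, direction, tri_a, tri_b, tri_c):
    """Per-origin count of ray/triangle intersections (Moller-Trumbore),
    vectorized over triangles for each origin."""
    d = direction / np.linalg.norm(direction)
    e1 = tri_b - tri_a
    e2 = tri_c - tri_a
    pvec = np.cross(d, e2)
    det = np.einsum("ij,ij->i", e1, pvec)
    ok = np.abs(det) > 1e-12
    counts = np.zeros(len(origins), dtype=np.int64)
    inv = np.zeros_like(det)
    inv[ok] = 1.0 / det[ok]
    for i, o in enumerate(origins):
        tvec = o - tri_a
        u = np.einsum("ij,ij->i", tvec, pvec) * inv
        qvec = np.cross(tvec, e1)
        v = np.einsum("j,ij->i", d, qvec) * inv
        t = np.einsum("ij,ij->i", e2, qvec) * inv
        hit = ok & (u >= 0) & (v >= 0) & (u + v <= 1) & (t > 1e-9)
        counts[i] = int(hit.sum())
    return counts


def point_to_mesh_distance(points, mesh: SurfaceMesh) -> np.ndarray:
    """Minimum Euclidean distance (mm) from each point to the surface,
    exact point-triangle distances over all triangles."""
    d, _ = _closest_points(points, mesh)
    return d


def closest_point_on_mesh(points, mesh: SurfaceMesh) -> np.ndarray:
    """Closest surface point (on some triangle) for each query point."""
    _, cp = _closest_points(points, mesh)
    return cp


def _closest_points(points, mesh: SurfaceMesh):
    points = np.atleast_2d(np.asarray(points, dtype=np.float64))
    a, b, c = mesh.triangle_corners()
    best_d = np.full(len(points), np.inf)
    best_p = np.zeros_like(points)
    for i, p in enumerate(points):
        cp = _closest_point_triangles(p, a, b, c)
        d2 = np.einsum("ij,ij->i", cp - p, cp - p)
        j = int(np.argmin(d2))
        best_d[i] = np.sqrt(d2[j])
        best_p[i] = cp[j]
    return best_d, best_p


def _closest_point_triangles(p, a, b, c):
    """Closest point to ``p`` on each triangle (Ericson's barycentric
    region test, vectorized over triangles)."""
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp_ = p - c
    d5 = np.einsum("ij,ij->i", ab, cp_)
    d6 = np.einsum("ij,ij->i", ac, cp_)
    vc = d1 * d4 - d3 * d2
    vb = d5 * d2 - d1 * d6
    va = d3 * d6 - d5 * d4
    out = np.zeros_like(a)
    done = np.zeros(len(a), dtype=bool)

    def put(mask, val):
        m = mask & ~done
        out[m] = val[m] if val.ndim == 2 else val
        done[m] = True

    put((d1 <= 0) & (d2 <= 0), a)
    put((d3 >= 0) & (d4 <= d3), b)
    put((d6 >= 0) & (d5 <= d6), c)
    with np.errstate(divide="ignore", invalid="ignore"):
        v_ab = np.where(d1 - d3 != 0, d1 / (d1 - d3), 0.0)
        put((vc <= 0) & (d1 >= 0) & (d3 <= 0), a + v_ab[:, None] * ab)
        w_ac = np.where(d2 - d6 != 0, d2 / (d2 - d6), 0.0)
        put((vb <= 0) & (d2 >= 0) & (d6 <= 0), a + w_ac[:, None] * ac)
        denom_bc = (d4 - d3) + (d5 - d6)
        w_bc = np.where(denom_bc != 0, (d4 - d3) / denom_bc, 0.0)
        put((va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0),
            b + w_bc[:, None] * (c - b))
        denom = va + vb + vc
        denom = np.where(denom != 0, denom, 1.0)
        v = vb / denom
        w = vc / denom
        put(np.ones(len(a), dtype=bool), a + ab * v[:, None] + ac * w[:, None])
    return out


def point_status(userdata: UserData, surface_tolerance: float = 3.0,
                 seed: int = 7) -> PointStatusResult:
    """Classify every electric point interior/exterior to the closed chamber.

    Classification uses crossing parity of a cast ray against the hole-filled
    mesh; three seeded random ray directions vote by majority so a ray that
    grazes an edge cannot flip the result.  ``surface_tolerance`` (mm) is
    reported alongside the min distance to the open surface; the in/out flag
    itself is strict.
    """
    if userdata.electric is None:
        raise MissingDataError("study has no electrical data")
    mesh = _mesh_of(userdata)
    closed = fill_holes(mesh)
    pts = userdata.electric.egm_x
    inside = points_inside_mesh(pts, closed, seed=seed)
    dist = point_to_mesh_distance(pts, mesh)
    return PointStatusResult(inside=inside, distance=dist,
                             surface_tolerance=float(surface_tolerance))


def points_inside_mesh(points, closed_mesh: SurfaceMesh, seed: int = 7,
                       n_rays: int = 3) -> np.ndarray:
    """Odd-parity containment test with majority vote over seeded rays."""
    points = np.atleast_2d(np.asarray(points, dtype=np.float64))
    rng = np.random.default_rng(seed)
    a, b, c = closed_mesh.triangle_corners()
    votes = np.zeros(len(points), dtype=np.int64)
    for _ in range(n_rays):
        d = rng.normal(size=3)
        counts = _ray_crossings(points, d, a, b, c)
        votes += counts % 2
    return votes * 2 > n_rays
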