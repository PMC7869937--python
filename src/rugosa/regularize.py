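"""Point-density regularization via a 2.5-D surface mesh.

SfM clouds have wildly varying density and holes. The canopy, viewed from
nadir, is a height field, so the cloud is meshed by Delaunay triangulation of
the (x, y) projection lifted to z, repaired, smoothed, resampled at a fixed
density (500 points/m^2 by default elsewhere in the pipeline) and finally
thinned by dart-throwing Poisson-disk sampling to a 1 cm minimum spacing.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections import defaultdict

import numpy as np
from scipy.spatial import Delaunay, QhullError, cKDTree

from .cloud import ColoredPointCloud

__all__ = [
    "SurfaceMesh", "build_mesh", "repair_holes", "laplacian_smooth",
    "sample_surface", "poisson_disk_thin",
]


@dataclass
class SurfaceMesh:
    """Triangle mesh with per-vertex color.

    vertices : (V, 3) float64, meters
    faces    : (F, 3) int vertex-index triples
    colors   : (V, 3) uint8
    """

    vertices: np.ndarray
    faces: np.ndarray
    colors: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64
                                             ).reshape(-1, 3)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64).reshape(-1, 3)
        self.colors = np.ascontiguousarray(self.colors, dtype=np.uint8).reshape(-1, 3)
        if len(self.colors) != len(self.vertices):
            raise ValueError("one color per vertex required")
        if self.faces.size and (self.faces.min() < 0
                                or self.faces.max() >= len(self.vertices)):
            raise ValueError("face indices out of range")

    def triangle_areas(self) -> np.ndarray:
        a, b, c = (self.vertices[self.faces[:, i]] for i in range(3))
        return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)

    @property
    def area(self) -> float:
        return float(self.triangle_areas().sum())

    def edge_counts(self) -> dict[tuple[int, int], int]:
        counts: dict[tuple[int, int], int] = defaultdict(int)
        for tri in self.faces:
            for i in range(3):
                u, v = int(tri[i]), int(tri[(i + 1) % 3])
                counts[(min(u, v), max(u, v))] += 1
        return counts

    def boundary_edges(self) -> list[tuple[int, int]]:
        return [e for e, c in self.edge_counts().items() if c == 1]

    def boundary_vertices(self) -> np.ndarray:
        edges = self.boundary_edges()
        if not edges:
            return np.empty(0, dtype=np.int64)
        return np.unique(np.asarray(edges).ravel())


def build_mesh(cloud: ColoredPointCloud,
               max_edge: float | None = None) -> SurfaceMesh:
    """Delaunay-triangulate the (x, y) projection of ``cloud`` lifted to z.

    The vertex set equals the cloud's point set; with ``max_edge=None`` the
    triangles cover the x-y convex hull. A canopy seen from nadir is a height
    field, but a hull-covering triangulation also spans data gaps and builds
    near-vertical "walls" between canopy and ground; passing ``max_edge``
    (meters) drops every triangle with a 3-D edge longer than that, so real
    coverage gaps stay open (to be treated by :func:`repair_holes`) and
    occlusion walls do not get resampled later. Raises on fewer than 3 points
    or a collinear projection.
    """
    if len(cloud) < 3:
        raise ValueError("meshing needs at least 3 points")
    try:
        tri = Delaunay(cloud.xyz[:, :2])
    except QhullError as exc:
        raise ValueError("projected points are collinear; cannot mesh") from exc
    if tri.simplices.size == 0:
        raise ValueError("projected points are collinear; cannot mesh")
    faces = tri.simplices.copy()
    if max_edge is not None:
        if max_edge <= 0:
            raise ValueError("max_edge must be positive")
        corners = cloud.xyz[faces]                      # (F, 3, 3)
        edge_len = np.linalg.norm(
            corners - np.roll(corners, -1, axis=1), axis=2)
        faces = faces[edge_len.max(axis=1) <= max_edge]
        if faces.size == 0:
            raise ValueError("max_edge pruned every triangle; increase it")
    return SurfaceMesh(cloud.xyz.copy(), faces, cloud.rgb.copy())


# --------------------------------------------------------------------------
# hole repair
# --------------------------------------------------------------------------

def _boundary_loops(mesh: SurfaceMesh) -> tuple[list[list[int]], int]:
    """Split boundary edges into closed vertex loops.

    Returns (loops, n_skipped) where loops are cyclic vertex index lists and
    n_skipped counts non-manifold boundary structures left alone.
    """
    adj: dict[int, list[int]] = defaultdict(list)
    for u, v in mesh.boundary_edges():
        adj[u].append(v)
        adj[v].append(u)
    n_skipped = 0
    bad = {v for v, nbrs in adj.items() if len(nbrs) != 2}
    visited: set[tuple[int, int]] = set()
    loops: list[list[int]] = []
    for start in sorted(adj):
        if start in bad:
            n_skipped += 1
            continue
        for nxt in adj[start]:
            if (start, nxt) in visited:
                continue
            loop = [start]
            prev, cur = start, nxt
            visited.update({(start, nxt), (nxt, start)})
            ok = True
            while cur != start:
                if cur in bad:
                    ok = False
                    break
                loop.append(cur)
                a, b = adj[cur]
                prev, cur = cur, (b if a == prev else a)
                visited.update({(prev, cur), (cur, prev)})
            if ok and len(loop) >= 3:
                loops.append(loop)
            elif not ok:
                n_skipped += 1
    return loops, n_skipped


def _loop_xy_area(mesh: SurfaceMesh, loop: list[int]) -> float:
    pts = mesh.vertices[loop][:, :2]
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def _loop_perimeter(mesh: SurfaceMesh, loop: list[int]) -> float:
    pts = mesh.vertices[loop]
    return float(np.linalg.norm(pts - np.roll(pts, -1, axis=0), axis=1).sum())


def _project_loop(points: np.ndarray) -> np.ndarray:
    """2-D coordinates of a loop in its best-fit plane."""
    centered = points - points.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    return centered @ vt[:2].T


def _ear_clip(coords2d: np.ndarray) -> list[tuple[int, int, int]]:
    """Triangulate a simple polygon (local indices) by ear clipping."""
    n = len(coords2d)
    if n < 3:
        return []
    # enforce CCW
    x, y = coords2d[:, 0], coords2d[:, 1]
    signed = 0.5 * (np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    order = list(range(n)) if signed >= 0 else list(range(n))[::-1]
    tris: list[tuple[int, int, int]] = []
    guard = 0
    while len(order) > 3 and guard < 10 * n:
        guard += 1
        clipped = False
        m = len(order)
        for j in range(m):
            i0, i1, i2 = order[j - 1], order[j], order[(j + 1) % m]
            a, b, c = coords2d[i0], coords2d[i1], coords2d[i2]
            cross = (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
            if cross <= 1e-14:
                continue  # reflex or degenerate corner
            others = [k for k in order if k not in (i0, i1, i2)]
            if others and _any_inside(coords2d[others], a, b, c):
                continue
            tris.append((i0, i1, i2))
            order.pop(j)
            clipped = True
            break
        if not clipped:  # numerically stuck: fan from first vertex
            for j in range(1, len(order) - 1):
                tris.append((order[0], order[j], order[j + 1]))
            return tris
    tris.append((order[0], order[1], order[2]))
    return tris


def _any_inside(pts: np.ndarray, a, b, c) -> bool:
    def side(p, q, r):
        return (q[0] - p[0]) * (r[:, 1] - p[1]) - (q[1] - p[1]) * (r[:, 0] - p[0])
    d1, d2, d3 = side(a, b, pts), side(b, c, pts), side(c, a, pts)
    return bool(np.any((d1 > 0) & (d2 > 0) & (d3 > 0)))


def repair_holes(mesh: SurfaceMesh, max_hole_perimeter: float = 0.5
                 ) -> tuple[SurfaceMesh, dict]:
    """Fill interior holes by planar triangulation of their boundary loops.

    Loops with perimeter above ``max_hole_perimeter`` (meters) and the outer
    boundary are left open; non-manifold loops are skipped. Vertex positions
    never change — only triangles are added.
    """
    loops, n_skipped = _boundary_loops(mesh)
    log = {"n_holes_filled": 0, "n_holes_left_open": 0,
           "n_nonmanifold_skipped": n_skipped}
    if len(loops) <= 1:  # outer boundary only (or nothing): no holes
        return mesh, log
    areas = [_loop_xy_area(mesh, lp) for lp in loops]
    outer = int(np.argmax(areas))
    new_faces = [mesh.faces]
    for i, loop in enumerate(loops):
        if i == outer:
            continue
        if _loop_perimeter(mesh, loop) > max_hole_perimeter:
            log["n_holes_left_open"] += 1
            continue
        coords = _project_loop(mesh.vertices[loop])
        tris = _ear_clip(coords)
        new_faces.append(np.asarray([[loop[a], loop[b], loop[c]]
                                     for a, b, c in tris], dtype=np.int64))
        log["n_holes_filled"] += 1
    repaired = SurfaceMesh(mesh.vertices, np.vstack(new_faces), mesh.colors)
    return repaired, log


# --------------------------------------------------------------------------
# smoothing
# --------------------------------------------------------------------------

def laplacian_smooth(mesh: SurfaceMesh, radius: float = 0.10,
                     iterations: int = 1,
                     vertex_mask: np.ndarray | None = None) -> SurfaceMesh:
    """Move each vertex to the centroid of mesh vertices within ``radius``.

    Boundary vertices stay fixed so the mesh outline is preserved;
    ``vertex_mask`` optionally restricts smoothing to selected vertices.
    Connectivity and colors are unchanged.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    movable = np.ones(len(mesh.vertices), dtype=bool)
    movable[mesh.boundary_vertices()] = False
    if vertex_mask is not None:
        movable &= np.asarray(vertex_mask, dtype=bool)
    verts = mesh.vertices.copy()
    for _ in range(iterations):
        tree = cKDTree(verts)
        groups = tree.query_ball_point(verts[movable], r=radius)
        new = np.array([verts[g].mean(axis=0) for g in groups])
        verts[movable] = new
    return SurfaceMesh(verts, mesh.faces, mesh.colors)


# --------------------------------------------------------------------------
# resampling
# --------------------------------------------------------------------------

def sample_surface(mesh: SurfaceMesh, density: float = 500.0,
                   seed: int | None = 0) -> ColoredPointCloud:
    """Draw round(density * area) points uniformly over the mesh surface.

    Triangles are chosen with probability proportional to their 3-D area and
    positions/colors interpolated barycentrically, so the sampled points lie
    exactly on the source triangles. Reproducible for a fixed seed.
    """
    areas = mesh.triangle_areas()
    total = float(areas.sum())
    if total <= 0:
        raise ValueError("mesh has zero surface area")
    n = int(round(density * total))
    rng = np.random.default_rng(seed)
    tri = rng.choice(len(mesh.faces), size=n, p=areas / total)
    r1 = np.sqrt(rng.random(n))
    r2 = rng.random(n)
    w = np.column_stack([1.0 - r1, r1 * (1.0 - r2), r1 * r2])  # barycentric
    corners = mesh.vertices[mesh.faces[tri]]                    # (n, 3, 3)
    xyz = np.einsum("nk,nkj->nj", w, corners)
    col = np.einsum("nk,nkj->nj", w, mesh.colors[mesh.faces[tri]].astype(float))
    rgb = np.clip(np.round(col), 0, 255).astype(np.uint8)
    return ColoredPointCloud(xyz, rgb, provenance="regularized")


def poisson_disk_thin(cloud: ColoredPointCloud, min_dist: float = 0.01,
                      seed: int | None = 0) -> ColoredPointCloud:
    """Dart-throwing Poisson-disk thinning with culling.

    Points are visited in a seeded random order; a point is accepted iff no
    previously accepted point lies closer than ``min_dist`` (3-D Euclidean).
    The result is maximal: every rejected point is within ``min_dist`` of an
    accepted one. Output keeps the original point order.
    """
    if min_dist <= 0:
        raise ValueError("min_dist must be positive")
    n = len(cloud)
    if n == 0:
        return cloud
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    cell = min_dist
    keys = np.floor(cloud.xyz / cell).astype(np.int64)
    grid: dict[tuple[int, int, int], list[int]] = defaultdict(list)
    accepted = np.zeros(n, dtype=bool)
    xyz = cloud.xyz
    for i in order:
        kx, ky, kz = keys[i]
        ok = True
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    for j in grid.get((kx + dx, ky + dy, kz + dz), ()):
                        d = xyz[i] - xyz[j]
                        if d[0] * d[0] + d[1] * d[1] + d[2] * d[2] < min_dist ** 2:
                            ok = False
                            break
                    if not ok:
                        break
                if not ok:
                    break
            if not ok:
                break
        if ok:
            accepted[i] = True
            grid[(int(kx), int(ky), int(kz))].append(int(i))
    return cloud.select(accepted)
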