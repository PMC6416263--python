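"""Low-level triangle-mesh helpers shared across the package.

Meshes are represented as :class:`trimesh.Trimesh` objects in physical
millimetre coordinates.  Helpers here stay purely array-based so that every
operation is deterministic and independent of trimesh's optional caches.
"""

from __future__ import annotations

import numpy as np
import trimesh
from scipy.spatial import cKDTree

__all__ = [
    "as_mesh",
    "signed_volume",
    "surface_area",
    "is_watertight",
    "euler_characteristic",
    "ensure_outward",
    "clip_halfspace_z",
    "max_planar_extent",
    "project_to_surface",
]


def as_mesh(vertices, faces) -> trimesh.Trimesh:
    """Wrap raw arrays without any of trimesh's automatic processing."""
    return trimesh.Trimesh(
        vertices=np.asarray(vertices, dtype=float),
        faces=np.asarray(faces, dtype=np.int64),
        process=False,
    )


def signed_volume(mesh: trimesh.Trimesh) -> float:
    """Signed enclosed volume via the divergence theorem.

    Sum of signed tetrahedra spanned by each face and the origin; positive
    for outward-oriented closed surfaces, translation invariant for closed
    meshes.
    """
    tri = mesh.vertices[mesh.faces]
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    return float(np.einsum("ij,ij->i", a, np.cross(b, c)).sum() / 6.0)


def surface_area(mesh: trimesh.Trimesh) -> float:
    """Total triangle area."""
    tri = mesh.vertices[mesh.faces]
    cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    return float(0.5 * np.linalg.norm(cross, axis=1).sum())


def _edges(faces: np.ndarray) -> np.ndarray:
    return np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])


def is_watertight(mesh: trimesh.Trimesh) -> bool:
    """True iff every undirected edge is shared by exactly two faces."""
    if len(mesh.faces) == 0:
        return False
    edges = np.sort(_edges(mesh.faces), axis=1)
    _, counts = np.unique(edges, axis=0, return_counts=True)
    return bool(np.all(counts == 2))


def euler_characteristic(mesh: trimesh.Trimesh) -> int:
    """V - E + F (2 for a genus-0 closed surface)."""
    edges = np.sort(_edges(mesh.faces), axis=1)
    n_e = len(np.unique(edges, axis=0))
    n_v = len(np.unique(mesh.faces))
    return int(n_v - n_e + len(mesh.faces))


def ensure_outward(mesh: trimesh.Trimesh) -> trimesh.Trimesh:
    """Flip all faces if the signed volume is negative."""
    if signed_volume(mesh) < 0:
        return as_mesh(mesh.vertices, mesh.faces[:, ::-1])
    return mesh


def clip_halfspace_z(mesh: trimesh.Trimesh, z0: float = 0.0, atol: float = 1e-9):
    """Keep the ``z >= z0`` part of a closed mesh and cap the cut.

    Triangles crossing the plane are split; the planar cut boundary is
    capped with a triangle fan around its centroid (valid for star-shaped
    cross sections, which covers every surface this package generates).

    Returns
    -------
    (mesh, boundary) : (trimesh.Trimesh, ndarray)
        The capped upper part and the ordered ``(n, 3)`` loop of boundary
        vertices lying on the cut plane.
    """
    v = np.asarray(mesh.vertices, dtype=float)
    f = np.asarray(mesh.faces, dtype=np.int64)
    z = v[:, 2] - z0
    scale = max(np.abs(z).max(), 1.0)
    z = np.where(np.abs(z) <= atol * scale, 0.0, z)

    new_vertices = [v.copy()]
    cut_cache: dict[tuple[int, int], int] = {}
    n_base = len(v)
    extra: list[np.ndarray] = []

    def cut_point(i: int, j: int) -> int:
        key = (i, j) if i < j else (j, i)
        idx = cut_cache.get(key)
        if idx is None:
            t = z[key[0]] / (z[key[0]] - z[key[1]])
            p = v[key[0]] + t * (v[key[1]] - v[key[0]])
            p[2] = z0
            idx = n_base + len(extra)
            extra.append(p)
            cut_cache[key] = idx
        return idx

    zf = z[f]
    # faces lying entirely in the cut plane (an existing cap) are dropped;
    # the cut is re-capped below, which makes the operation idempotent
    kept_mask = np.all(zf >= 0, axis=1) & ~np.all(zf == 0, axis=1)
    drop_mask = ~kept_mask & np.all(zf <= 0, axis=1)
    cross_idx = np.nonzero(~kept_mask & ~drop_mask)[0]

    kept_faces: list[tuple[int, int, int]] = [tuple(t) for t in f[kept_mask]]
    boundary_edges: list[tuple[int, int]] = []

    # plane edges of fully-kept faces, directed along the face winding
    for k in range(3):
        i_col = f[kept_mask][:, k]
        j_col = f[kept_mask][:, (k + 1) % 3]
        on = (z[i_col] == 0) & (z[j_col] == 0)
        boundary_edges.extend(zip(i_col[on].tolist(), j_col[on].tolist()))

    for tri in f[cross_idx]:
        # triangle crosses the plane: clip to the z>=0 polygon
        poly: list[int] = []
        for k in range(3):
            i, j = tri[k], tri[(k + 1) % 3]
            if z[i] >= 0:
                poly.append(int(i))
            if (z[i] > 0 and z[j] < 0) or (z[i] < 0 and z[j] > 0):
                poly.append(cut_point(int(i), int(j)))
        # the two polygon vertices on the plane form a boundary edge,
        # in polygon winding order
        def _z(idx: int) -> float:
            return z[idx] if idx < n_base else 0.0

        plane_pts = [p for p in poly if _z(p) == 0]
        if len(plane_pts) == 2:
            a, b = plane_pts
            ia, ib = poly.index(a), poly.index(b)
            if (ia + 1) % len(poly) == ib:
                boundary_edges.append((a, b))
            else:
                boundary_edges.append((b, a))
        if len(poly) == 3:
            kept_faces.append((poly[0], poly[1], poly[2]))
        elif len(poly) == 4:
            kept_faces.append((poly[0], poly[1], poly[2]))
            kept_faces.append((poly[0], poly[2], poly[3]))

    if not kept_faces or not boundary_edges:
        raise ValueError("cut plane does not intersect the mesh")

    all_v = np.vstack([new_vertices[0]] + [np.asarray(extra)]) if extra else v
    # chain boundary edges into an ordered loop
    nxt = {a: b for a, b in boundary_edges}
    start = boundary_edges[0][0]
    loop = [start]
    cur = nxt[start]
    while cur != start:
        loop.append(cur)
        cur = nxt.get(cur)
        if cur is None or len(loop) > len(boundary_edges) + 1:
            raise ValueError("cut boundary is not a single closed loop")
    loop_pts = all_v[loop]

    # fan cap around the loop centroid; cap normals must face -z, which for
    # a boundary wound consistently with outward upper-surface normals means
    # traversing the loop in reverse
    centroid = loop_pts.mean(axis=0)
    centroid[2] = z0
    ci = len(all_v)
    all_v = np.vstack([all_v, centroid[None, :]])
    n = len(loop)
    for k in range(n):
        a, b = loop[k], loop[(k + 1) % n]
        kept_faces.append((ci, b, a))

    faces = np.asarray(kept_faces, dtype=np.int64)
    # drop unreferenced vertices, keeping first-use order deterministic
    used, inverse = np.unique(faces, return_inverse=True)
    remap_faces = inverse.reshape(faces.shape)
    out = as_mesh(all_v[used], remap_faces)
    out = ensure_outward(out)
    loop_local = np.searchsorted(used, np.asarray(loop))
    return out, out.vertices[loop_local]


def max_planar_extent(points: np.ndarray) -> float:
    """Maximal pairwise XY distance (caliper diameter) of a point set."""
    pts = np.asarray(points, dtype=float)[:, :2]
    if len(pts) > 400:
        from scipy.spatial import ConvexHull

        pts = pts[ConvexHull(pts).vertices]
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
    return float(np.sqrt(d2.max()))


def _closest_on_triangles(points: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Closest point on each triangle ``tri[i]`` to ``points[i]`` (vectorized).

    Standard barycentric region classification (Ericson).
    """
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab, ac, ap = b - a, c - a, points - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = points - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = points - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    result = np.empty_like(points)
    done = np.zeros(len(points), dtype=bool)

    m = (d1 <= 0) & (d2 <= 0)
    result[m] = a[m]
    done |= m
    m = (~done) & (d3 >= 0) & (d4 <= d3)
    result[m] = b[m]
    done |= m
    vc = d1 * d4 - d3 * d2
    m = (~done) & (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = d1 / (d1 - d3)
    result[m] = a[m] + t[m, None] * ab[m]
    done |= m
    m = (~done) & (d6 >= 0) & (d5 <= d6)
    result[m] = c[m]
    done |= m
    vb = d5 * d2 - d1 * d6
    m = (~done) & (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = d2 / (d2 - d6)
    result[m] = a[m] + t[m, None] * ac[m]
    done |= m
    va = d3 * d6 - d5 * d4
    m = (~done) & (va <= 0) & ((d4 - d3) >= 0) & ((d5 - d6) >= 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (d4 - d3) / ((d4 - d3) + (d5 - d6))
    result[m] = b[m] + t[m, None] * (c[m] - b[m])
    done |= m
    m = ~done
    denom = va + vb + vc
    with np.errstate(invalid="ignore", divide="ignore"):
        v = vb / denom
        w = vc / denom
    result[m] = a[m] + v[m, None] * ab[m] + w[m, None] * ac[m]
    return result


class SurfaceProjector:
    """Project points onto a reference triangle mesh.

    Candidate triangles come from a KD-tree on triangle centroids; the exact
    closest point among the ``k`` nearest candidates is returned.
    """

    def __init__(self, mesh: trimesh.Trimesh, k: int = 8):
        self.triangles = np.asarray(mesh.vertices, dtype=float)[
            np.asarray(mesh.faces, dtype=np.int64)
        ]
        self.k = min(k, len(self.triangles))
        self.tree = cKDTree(self.triangles.mean(axis=1))

    def __call__(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        _, idx = self.tree.query(points, k=self.k)
        if self.k == 1:
            idx = idx[:, None]
        best = np.full(len(points), np.inf)
        out = np.empty_like(points)
        for col in range(idx.shape[1]):
            tri = self.triangles[idx[:, col]]
            cand = _closest_on_triangles(points, tri)
            d = ((cand - points) ** 2).sum(axis=1)
            better = d < best
            best[better] = d[better]
            out[better] = cand[better]
        return out


def project_to_surface(points: np.ndarray, mesh: trimesh.Trimesh, k: int = 8):
    """One-shot convenience wrapper around :class:`SurfaceProjector`."""
    return SurfaceProjector(mesh, k=k)(points)
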