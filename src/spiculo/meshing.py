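"""The four surface-reconstruction strategies M1-M4 and the convex hull.

M1  isosurface        marching cubes on the 0/1 field at isovalue 0.9
M2  isosurface filter M1 followed by one curvature-weighted smoothing pass
M3  isosurface remesh M1 followed by one isotropic remeshing pass at a
                      target edge length
M4  boundary          concave hull (alpha complex) around a point set; a
                      shrink factor of 1 selects the tightest single-component
                      closed boundary, 0 the convex hull

All reconstructed meshes are closed, outward-oriented triangulations in
physical millimetres.
"""

from __future__ import annotations

import warnings

import numpy as np
import trimesh
from scipy.spatial import ConvexHull, Delaunay
from skimage import measure

from .geometry import (
    SurfaceProjector,
    as_mesh,
    ensure_outward,
    is_watertight,
    signed_volume,
)
from .masks import BinaryMask

__all__ = [
    "mesh_isosurface",
    "smooth_mesh",
    "remesh_isotropic",
    "concave_hull",
    "convex_hull",
    "reconstruct",
]


def mesh_isosurface(mask: BinaryMask, isovalue: float = 0.9) -> trimesh.Trimesh:
    """M1: marching-cubes isosurface of the binary field.

    On a 0/1 field an isovalue of 0.9 places vertices 90 % of the way from
    each background voxel center toward its foreground neighbor, shrinking
    the surface relative to the mid-level 0.5.
    """
    if not 0 < isovalue < 1:
        raise ValueError("isovalue must lie in (0, 1)")
    field = mask.values.astype(np.float32)
    if field.max() <= isovalue:
        raise ValueError("empty isosurface")
    verts, faces, _, _ = measure.marching_cubes(
        field, level=isovalue, spacing=mask.spacing
    )
    verts = verts + np.asarray(mask.origin)
    mesh = ensure_outward(as_mesh(verts, faces))
    if signed_volume(mesh) <= 0:
        raise ValueError("degenerate isosurface")
    return mesh


def _vertex_adjacency(n_vertices: int, faces: np.ndarray):
    neighbors = [set() for _ in range(n_vertices)]
    for a, b, c in faces:
        neighbors[a].update((b, c))
        neighbors[b].update((a, c))
        neighbors[c].update((a, b))
    return neighbors


def _vertex_normals(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    tri = vertices[faces]
    fn = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    vn = np.zeros_like(vertices)
    for k in range(3):
        np.add.at(vn, faces[:, k], fn)
    norm = np.linalg.norm(vn, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    return vn / norm


def smooth_mesh(
    mesh: trimesh.Trimesh, iterations: int = 1, quantity: float = 5.0
) -> trimesh.Trimesh:
    """M2: curvature-weighted smoothing along vertex normals.

    Each pass estimates the mean-curvature normal by the umbrella Laplacian,
    normalizes the per-vertex curvature magnitude to [0, 1] over the mesh,
    and displaces each vertex along its normal by

        step = quantity * 0.01 * (mean edge length) * normalized curvature

    so high-curvature spicules move most while near-uniform-curvature
    regions barely shrink.  Topology is unchanged.  A displacement producing
    self-intersections is not prevented; it is the caller's concern (and is
    flagged as a warning by the experiment driver).
    """
    if quantity < 0:
        raise ValueError("quantity must be non-negative")
    v = np.asarray(mesh.vertices, dtype=float).copy()
    f = np.asarray(mesh.faces, dtype=np.int64)
    if quantity == 0 or iterations == 0:
        return as_mesh(v, f)
    neighbors = _vertex_adjacency(len(v), f)
    nb_idx = [np.fromiter(s, dtype=np.int64) for s in neighbors]
    edges = np.unique(np.sort(np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]]), axis=1), axis=0)
    for _ in range(iterations):
        mean_edge = float(
            np.linalg.norm(v[edges[:, 0]] - v[edges[:, 1]], axis=1).mean()
        )
        normals = _vertex_normals(v, f)
        lap = np.empty_like(v)
        for i, nb in enumerate(nb_idx):
            lap[i] = v[nb].mean(axis=0) - v[i]
        curv = np.einsum("ij,ij->i", lap, normals)
        peak = np.abs(curv).max()
        if peak == 0:
            break
        weights = curv / peak
        v = v + (quantity * 0.01 * mean_edge) * weights[:, None] * normals
    return as_mesh(v, f)


class _EditableMesh:
    """Minimal manifold triangle mesh supporting split/collapse/flip."""

    def __init__(self, vertices: np.ndarray, faces: np.ndarray):
        self.v: list[np.ndarray] = [p for p in np.asarray(vertices, dtype=float)]
        self.faces: dict[int, tuple[int, int, int]] = {
            i: tuple(t) for i, t in enumerate(np.asarray(faces, dtype=np.int64))
        }
        self.next_fid = len(self.faces)
        self.v2f: list[set] = [set() for _ in self.v]
        for fid, tri in self.faces.items():
            for t in tri:
                self.v2f[t].add(fid)

    # -- queries ----------------------------------------------------------
    def edge_faces(self, a: int, b: int) -> list[int]:
        return [
            fid
            for fid in self.v2f[a] & self.v2f[b]
        ]

    def vertex_neighbors(self, a: int) -> set:
        out = set()
        for fid in self.v2f[a]:
            out.update(self.faces[fid])
        out.discard(a)
        return out

    def edges(self):
        seen = set()
        for tri in self.faces.values():
            for k in range(3):
                e = tuple(sorted((tri[k], tri[(k + 1) % 3])))
                if e not in seen:
                    seen.add(e)
        return seen

    def edge_length(self, e) -> float:
        return float(np.linalg.norm(self.v[e[0]] - self.v[e[1]]))

    # -- edits ------------------------------------------------------------
    def add_face(self, tri) -> None:
        fid = self.next_fid
        self.next_fid += 1
        self.faces[fid] = tuple(int(t) for t in tri)
        for t in self.faces[fid]:
            self.v2f[t].add(fid)

    def remove_face(self, fid: int) -> None:
        for t in self.faces.pop(fid):
            self.v2f[t].discard(fid)

    def split_edge(self, a: int, b: int) -> int | None:
        fids = self.edge_faces(a, b)
        if len(fids) != 2:
            return None
        mid = 0.5 * (self.v[a] + self.v[b])
        m = len(self.v)
        self.v.append(mid)
        self.v2f.append(set())
        for fid in fids:
            tri = self.faces[fid]
            self.remove_face(fid)
            # replace edge (a,b) by (a,m),(m,b) preserving winding
            idx = {t: k for k, t in enumerate(tri)}
            ia, ib = idx[a], idx[b]
            if (ia + 1) % 3 == ib:
                c = tri[(ib + 1) % 3]
                self.add_face((a, m, c))
                self.add_face((m, b, c))
            else:
                c = tri[(ia + 1) % 3]
                self.add_face((b, m, c))
                self.add_face((m, a, c))
        return m

    def can_collapse(self, a: int, b: int) -> bool:
        fids = self.edge_faces(a, b)
        if len(fids) != 2:
            return False
        opposite = set()
        for fid in fids:
            opposite.update(self.faces[fid])
        opposite -= {a, b}
        common = self.vertex_neighbors(a) & self.vertex_neighbors(b)
        return common == opposite  # link condition

    def collapse_edge(self, a: int, b: int) -> bool:
        """Collapse b into the midpoint of (a, b); a survives."""
        if not self.can_collapse(a, b):
            return False
        mid = 0.5 * (self.v[a] + self.v[b])
        for fid in self.edge_faces(a, b):
            self.remove_face(fid)
        self.v[a] = mid
        for fid in list(self.v2f[b]):
            tri = self.faces[fid]
            self.remove_face(fid)
            self.add_face(tuple(a if t == b else t for t in tri))
        return True

    def flip_edge(self, a: int, b: int) -> bool:
        fids = self.edge_faces(a, b)
        if len(fids) != 2:
            return False
        f0, f1 = fids
        c = [t for t in self.faces[f0] if t not in (a, b)][0]
        d = [t for t in self.faces[f1] if t not in (a, b)][0]
        if c == d or d in self.vertex_neighbors(c):
            return False
        tri0 = self.faces[f0]
        # winding: rebuild both faces around the new diagonal (c, d)
        idx = {t: k for k, t in enumerate(tri0)}
        if (idx[a] + 1) % 3 == idx[b]:
            newf0, newf1 = (a, d, c), (b, c, d)
        else:
            newf0, newf1 = (a, c, d), (b, d, c)
        self.remove_face(f0)
        self.remove_face(f1)
        self.add_face(newf0)
        self.add_face(newf1)
        return True

    def valence(self, a: int) -> int:
        return len(self.vertex_neighbors(a))

    def to_mesh(self) -> trimesh.Trimesh:
        faces = np.asarray(
            [self.faces[fid] for fid in sorted(self.faces)], dtype=np.int64
        )
        verts = np.asarray(self.v)
        used, inverse = np.unique(faces, return_inverse=True)
        return as_mesh(verts[used], inverse.reshape(faces.shape))


def remesh_isotropic(
    mesh: trimesh.Trimesh,
    target_edge: float = 2.0,
    iterations: int = 1,
    relax: float = 0.5,
) -> trimesh.Trimesh:
    """M3: one (or more) passes of isotropic remeshing.

    Each pass: split edges longer than 4/3 of the target, collapse edges
    shorter than 4/5 of the target (skipping any collapse that would break
    the manifold link condition or create an over-long edge), flip edges to
    regularize vertex valences toward 6, then tangentially relax vertices
    and project them back onto the input surface.  Deterministic: edges are
    processed in sorted order.
    """
    if target_edge <= 0:
        raise ValueError("target_edge must be positive")
    hi = 4.0 / 3.0 * target_edge
    lo = 4.0 / 5.0 * target_edge
    em = _EditableMesh(mesh.vertices, mesh.faces)
    projector = SurfaceProjector(mesh)

    for _ in range(iterations):
        # split pass, longest first
        edges = sorted(em.edges(), key=lambda e: (-em.edge_length(e), e))
        for e in edges:
            if e[0] < len(em.v) and e[1] < len(em.v) and em.edge_length(e) > hi:
                if em.edge_faces(*e):
                    em.split_edge(*e)
        # collapse pass, shortest first; recheck length at pop time
        edges = sorted(em.edges(), key=lambda e: (em.edge_length(e), e))
        for a, b in edges:
            if not em.edge_faces(a, b):
                continue
            if em.edge_length((a, b)) >= lo:
                continue
            # avoid creating over-long edges from the merged vertex
            mid = 0.5 * (em.v[a] + em.v[b])
            nbs = (em.vertex_neighbors(a) | em.vertex_neighbors(b)) - {a, b}
            if any(np.linalg.norm(em.v[n] - mid) > hi for n in nbs):
                continue
            em.collapse_edge(a, b)
        # flip pass for valence regularization
        for a, b in sorted(em.edges()):
            fids = em.edge_faces(a, b)
            if len(fids) != 2:
                continue
            c = [t for t in em.faces[fids[0]] if t not in (a, b)][0]
            d = [t for t in em.faces[fids[1]] if t not in (a, b)][0]
            dev_now = sum((em.valence(x) - 6) ** 2 for x in (a, b, c, d))
            dev_flip = (
                (em.valence(a) - 7) ** 2
                + (em.valence(b) - 7) ** 2
                + (em.valence(c) - 5) ** 2
                + (em.valence(d) - 5) ** 2
            )
            if dev_flip < dev_now:
                em.flip_edge(a, b)
        # tangential relaxation + projection back to the source surface
        out = em.to_mesh()
        v = np.asarray(out.vertices)
        f = np.asarray(out.faces)
        normals = _vertex_normals(v, f)
        nb_idx = _vertex_adjacency(len(v), f)
        cent = np.empty_like(v)
        for i, s in enumerate(nb_idx):
            cent[i] = v[np.fromiter(s, dtype=np.int64)].mean(axis=0)
        disp = cent - v
        disp -= np.einsum("ij,ij->i", disp, normals)[:, None] * normals
        v = v + relax * disp
        v = projector(v)
        em = _EditableMesh(v, f)

    result = em.to_mesh()
    if not is_watertight(result):
        warnings.warn("remeshed surface is not watertight", stacklevel=2)
    return ensure_outward(result)


def _tet_circumradii(points: np.ndarray, tets: np.ndarray) -> np.ndarray:
    a = points[tets[:, 0]]
    rows = points[tets[:, 1:]] - a[:, None, :]  # (n, 3, 3)
    sq = np.einsum("nij,nij->ni", rows, rows)
    det = np.linalg.det(rows)
    scale = np.abs(sq).max(axis=1) ** 1.5 + 1e-30
    good = np.abs(det) > 1e-12 * scale
    r = np.empty(len(tets))
    if np.any(good):
        # circumcenter offset c solves 2 rows . c = sq
        c = np.linalg.solve(2.0 * rows[good], sq[good][..., None])[..., 0]
        r[good] = np.linalg.norm(c, axis=1)
    if np.any(~good):
        # flat slivers (common on lattice-aligned points): the circumsphere
        # degenerates, so use half the tet diameter as its finite limit
        p = points[tets[~good]]
        d2 = ((p[:, :, None, :] - p[:, None, :, :]) ** 2).sum(axis=-1)
        r[~good] = 0.5 * np.sqrt(d2.reshape(len(p), -1).max(axis=1))
    r[~np.isfinite(r)] = np.inf
    return r


def _boundary_faces(tets: np.ndarray, keep: np.ndarray, points: np.ndarray):
    """Oriented boundary faces of the kept tetrahedra."""
    kept = tets[keep]
    faces = []
    owners = []
    for k, opp in enumerate(range(4)):
        idx = [i for i in range(4) if i != opp]
        faces.append(kept[:, idx])
        owners.append(kept[:, opp])
    faces = np.concatenate(faces)
    owners = np.concatenate(owners)
    key = np.sort(faces, axis=1)
    _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
    on_boundary = counts[inv] == 1
    bf = faces[on_boundary]
    own = owners[on_boundary]
    # orient each face so its normal points away from the owning vertex
    tri = points[bf]
    n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    to_owner = points[own] - tri[:, 0]
    flip = np.einsum("ij,ij->i", n, to_owner) > 0
    bf[flip] = bf[flip][:, ::-1]
    return bf


def _alpha_ok(tets, keep, points, coverable, require_manifold):
    if not np.any(keep):
        return False
    kept = tets[keep]
    if not np.array_equal(np.unique(kept), coverable):
        return False
    # face-connectivity of kept tets via union-find
    parent = np.arange(keep.sum())
    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    face_map: dict[tuple, int] = {}
    for ti, tet in enumerate(kept):
        for opp in range(4):
            fkey = tuple(sorted(np.delete(tet, opp)))
            other = face_map.setdefault(fkey, ti)
            if other != ti:
                ra, rb = find(ti), find(other)
                if ra != rb:
                    parent[ra] = rb
    roots = {find(i) for i in range(len(kept))}
    if len(roots) != 1:
        return False
    if require_manifold:
        bf = _boundary_faces(tets, keep, points)
        edges = np.sort(
            np.concatenate([bf[:, [0, 1]], bf[:, [1, 2]], bf[:, [2, 0]]]), axis=1
        )
        _, counts = np.unique(edges, axis=0, return_counts=True)
        if not np.all(counts == 2):
            return False
    return True


def concave_hull(points: np.ndarray, shrink_factor: float = 1.0) -> trimesh.Trimesh:
    """M4: single conforming closed boundary around a 3D point set.

    Implemented as an alpha complex over the Delaunay tetrahedralization.
    ``shrink_factor = 1`` selects the smallest alpha whose kept complex is a
    single face-connected component using every input point with an
    edge-manifold boundary (the tightest concave envelope); ``shrink_factor
    = 0`` corresponds to alpha = infinity, i.e. the convex hull.
    Intermediate values interpolate on the sorted circumradius scale.
    """
    points = np.asarray(points, dtype=float)
    if len(points) < 4:
        raise ValueError("need at least 4 points")
    if not 0 <= shrink_factor <= 1:
        raise ValueError("shrink_factor must lie in [0, 1]")
    if shrink_factor == 0:
        return convex_hull(points)
    try:
        dela = Delaunay(points)
    except Exception as exc:  # qhull degenerate input
        raise ValueError(f"degenerate (coplanar?) point set: {exc}") from exc
    tets = dela.simplices
    radii = _tet_circumradii(points, tets)
    finite = np.unique(radii[np.isfinite(radii)])
    # points incident only to degenerate (flat) tets cannot be covered by
    # any alpha complex; coverage is required over the rest
    coverable = np.unique(tets[np.isfinite(radii)])

    # smallest alpha (by bisection over the sorted radius scale) giving a
    # connected, all-points complex
    lo_i, hi_i = 0, len(finite) - 1
    if not _alpha_ok(tets, radii <= finite[hi_i], points, coverable, False):
        raise ValueError("no alpha yields a single closed boundary")
    while lo_i < hi_i:
        mid = (lo_i + hi_i) // 2
        if _alpha_ok(tets, radii <= finite[mid], points, coverable, False):
            hi_i = mid
        else:
            lo_i = mid + 1
    # walk upward until the boundary is also edge-manifold
    alpha_idx = lo_i
    while alpha_idx < len(finite) and not _alpha_ok(
        tets, radii <= finite[alpha_idx], points, coverable, True
    ):
        alpha_idx += 1
    if alpha_idx >= len(finite):
        raise ValueError("no alpha yields an edge-manifold boundary")
    if shrink_factor < 1:
        # interpolate toward the convex hull on the radius rank scale
        span = len(finite) - 1 - alpha_idx
        alpha_idx = alpha_idx + int(round((1.0 - shrink_factor) * span))
    keep = radii <= finite[alpha_idx]
    bf = _boundary_faces(tets, keep, points)
    used, inverse = np.unique(bf, return_inverse=True)
    return ensure_outward(as_mesh(points[used], inverse.reshape(bf.shape)))


def convex_hull(points: np.ndarray) -> trimesh.Trimesh:
    """Convex hull triangulation with outward-oriented faces."""
    points = np.asarray(points, dtype=float)
    if len(points) < 4:
        raise ValueError("need at least 4 points")
    try:
        hull = ConvexHull(points)
    except Exception as exc:
        raise ValueError(f"degenerate (coplanar?) point set: {exc}") from exc
    faces = hull.simplices
    centroid = points[hull.vertices].mean(axis=0)
    tri = points[faces]
    n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    outward = np.einsum("ij,ij->i", n, tri[:, 0] - centroid) < 0
    faces[outward] = faces[outward][:, ::-1]
    used, inverse = np.unique(faces, return_inverse=True)
    return ensure_outward(as_mesh(points[used], inverse.reshape(faces.shape)))


def reconstruct(
    mask: BinaryMask,
    method: str = "M1",
    isovalue: float = 0.9,
    quantity: float = 5.0,
    smooth_iterations: int = 1,
    target_edge: float = 2.0,
    remesh_iterations: int = 1,
) -> trimesh.Trimesh:
    """Dispatch a meshing method name (M1-M4) on a binary mask."""
    method = method.upper()
    if method == "M1":
        return mesh_isosurface(mask, isovalue)
    if method == "M2":
        return smooth_mesh(
            mesh_isosurface(mask, isovalue), smooth_iterations, quantity
        )
    if method == "M3":
        return remesh_isotropic(
            mesh_isosurface(mask, isovalue), target_edge, remesh_iterations
        )
    if method == "M4":
        # boundary around the isosurface vertex cloud; using surface points
        # rather than all voxel centers keeps the Delaunay complex small
        return concave_hull(
            np.asarray(mesh_isosurface(mask, isovalue).vertices), shrink_factor=1.0
        )
    raise ValueError(f"unknown meshing method {method!r}")
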