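"""Triangulated colony surface and accretive layer construction.

The growing colony is represented as a closed triangulated surface whose
vertices stand for individual polyps.  Growth happens by *accretion*: each
vertex is displaced along its outward unit normal by a locally computed
extension length, depositing a new skeletal layer on top of the previous
one.  The substratum is the plane ``z = 0``; vertices on it (the clipped
rim and the basal cap) are anchored and never move.

Coordinate convention: z up, substratum at z = 0, ambient flow along +x.
All lengths are metres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh

_Z_TOL = 1e-9


@dataclass
class TriSurface:
    """Closed 2-manifold triangle mesh with per-vertex polyp state.

    Attributes
    ----------
    vertices : (n, 3) float array
        Vertex positions in metres.
    faces : (m, 3) int array
        Counter-clockwise (outward-facing) triangle index triples.
    fixed : (n,) bool array
        Substratum-anchored vertices (rim and basal cap); these never
        accrete.
    vertex_data : dict of str -> (n,) float array
        Arbitrary per-vertex scalar channels (absorbed flux, translocated
        nutrient concentration, ...).  Interpolated through remeshing.
    metadata : dict
        Free-form bookkeeping (remesh counts, self-intersection flags).
    """

    vertices: np.ndarray
    faces: np.ndarray
    fixed: np.ndarray
    vertex_data: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        self.fixed = np.asarray(self.fixed, dtype=bool)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (n, 3)")
        if len(self.fixed) != len(self.vertices):
            raise ValueError("fixed flag length mismatch")

    # -- basic queries ----------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def edges_unique(self) -> np.ndarray:
        """Unique undirected edges as a (k, 2) sorted-index array."""
        e = np.vstack([self.faces[:, [0, 1]], self.faces[:, [1, 2]],
                       self.faces[:, [2, 0]]])
        e.sort(axis=1)
        return np.unique(e, axis=0)

    def edge_lengths(self) -> np.ndarray:
        e = self.edges_unique()
        return np.linalg.norm(self.vertices[e[:, 0]] - self.vertices[e[:, 1]],
                              axis=1)

    def boundary_edges(self) -> np.ndarray:
        """Edges bounded by a single triangle (empty for a closed mesh)."""
        e = np.vstack([self.faces[:, [0, 1]], self.faces[:, [1, 2]],
                       self.faces[:, [2, 0]]])
        e.sort(axis=1)
        uniq, counts = np.unique(e, axis=0, return_counts=True)
        return uniq[counts == 1]

    def is_closed(self) -> bool:
        return len(self.boundary_edges()) == 0

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices.copy(), self.faces.copy(),
                               process=False)

    def copy(self) -> "TriSurface":
        return TriSurface(self.vertices.copy(), self.faces.copy(),
                          self.fixed.copy(),
                          {k: v.copy() for k, v in self.vertex_data.items()},
                          dict(self.metadata))

    def max_extent(self) -> float:
        """Maximum linear extent (bounding-box diagonal axis maximum)."""
        span = self.vertices.max(axis=0) - self.vertices.min(axis=0)
        return float(span.max())


@dataclass
class GrowthLayer:
    """Per-vertex extension lengths of one accretive layer."""

    lengths: np.ndarray  # (n,) metres, >= 0

    def __post_init__(self) -> None:
        self.lengths = np.asarray(self.lengths, dtype=float)


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

def geodesic_sphere(radius: float, frequency: int, relax: int = 60
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Class-I geodesic subdivision of the icosahedron.

    Unlike repeated 1->4 subdivision (frequencies restricted to powers of
    two) any integer frequency is allowed, so the edge length can be matched
    to a requested target within ~1/(2f) relative error.  A few rounds of
    tangential Laplacian relaxation even out the projection distortion.
    """
    if frequency < 1:
        raise ValueError("frequency must be >= 1")
    ico = trimesh.creation.icosahedron()
    base_v = np.asarray(ico.vertices, dtype=float)
    base_f = np.asarray(ico.faces)

    f = frequency
    verts: list[np.ndarray] = []
    faces: list[list[int]] = []
    index: dict[tuple, int] = {}

    def vid(p: np.ndarray) -> int:
        key = tuple(np.round(p, 9))
        i = index.get(key)
        if i is None:
            i = len(verts)
            index[key] = i
            verts.append(p)
        return i

    for tri in base_f:
        a, b, c = base_v[tri]
        # barycentric lattice of the face
        grid = {}
        for i in range(f + 1):
            for j in range(f + 1 - i):
                k = f - i - j
                p = (i * a + j * b + k * c) / f
                grid[(i, j)] = vid(p / np.linalg.norm(p))
        for i in range(f):
            for j in range(f - i):
                v0 = grid[(i, j)]
                v1 = grid[(i + 1, j)]
                v2 = grid[(i, j + 1)]
                faces.append([v0, v1, v2])
                if j < f - i - 1:
                    v3 = grid[(i + 1, j + 1)]
                    faces.append([v1, v3, v2])

    v = np.array(verts)
    fc = np.array(faces, dtype=np.int64)

    # spring relaxation towards uniform edge length, reprojected to the
    # sphere each step; brings max/min edge ratio down to ~1.26
    if relax > 0:
        e = np.vstack([fc[:, [0, 1]], fc[:, [1, 2]], fc[:, [2, 0]]])
        e = np.unique(np.sort(e, axis=1), axis=0)
        for _ in range(relax):
            d = v[e[:, 1]] - v[e[:, 0]]
            ln = np.linalg.norm(d, axis=1)
            force = (ln - ln.mean())[:, None] * d / ln[:, None]
            acc = np.zeros_like(v)
            np.add.at(acc, e[:, 0], force)
            np.add.at(acc, e[:, 1], -force)
            v = v + 0.2 * acc
            v /= np.linalg.norm(v, axis=1)[:, None]

    # outward orientation
    fv = v[fc]
    vol6 = np.einsum("ij,ij->i", fv[:, 0], np.cross(fv[:, 1], fv[:, 2])).sum()
    if vol6 < 0:
        fc = fc[:, ::-1]
    return v * radius, fc


def _fill_disk(rim: np.ndarray, target_edge: float) -> tuple[np.ndarray, np.ndarray]:
    """Triangulate the planar z=0 disk bounded by the (ordered) rim loop.

    Interior points are laid out on concentric rings spaced ~target_edge so
    cap triangles match the resolution of the spherical part.  Returns
    (points, triangles) with points including the rim first.
    """
    from scipy.spatial import Delaunay

    center = rim[:, :2].mean(axis=0)
    r_out = np.linalg.norm(rim[:, :2] - center, axis=1).min() - 0.35 * target_edge
    pts2 = [rim[:, :2]]
    n_rings = max(0, int(np.floor(r_out / target_edge)))
    for i in range(n_rings):
        r = r_out * (n_rings - i) / (n_rings + 0.0) if n_rings else 0.0
        if r < 0.45 * target_edge:
            continue
        n_pts = max(6, int(np.round(2 * np.pi * r / target_edge)))
        th = np.linspace(0, 2 * np.pi, n_pts, endpoint=False) + 0.1 * i
        pts2.append(center + r * np.column_stack([np.cos(th), np.sin(th)]))
    pts2.append(center[None, :])
    flat = np.vstack(pts2)
    tri = Delaunay(flat)
    simplices = tri.simplices
    # drop slivers outside the rim polygon (convex rim: Delaunay hull == rim)
    pts3 = np.column_stack([flat, np.zeros(len(flat))])
    # orient cap downward (outward normal -z for the bottom of the colony)
    a, b, c = pts3[simplices[:, 0]], pts3[simplices[:, 1]], pts3[simplices[:, 2]]
    nz = np.cross(b - a, c - a)[:, 2]
    simplices = np.where(nz[:, None] > 0, simplices[:, ::-1], simplices)
    return pts3, simplices


def make_initial_colony(diameter: float, target_edge: float,
                        center_height: float | None = None,
                        center_xy: tuple[float, float] = (0.0, 0.0)
                        ) -> TriSurface:
    """Triangulated sphere of given diameter clipped by the substratum.

    The sphere centre sits ``center_height`` above the plane z = 0 (default:
    one sixth of the diameter, so the colony "sits" on the substratum); the
    submerged cap is removed and replaced by a flat basal disk.  Rim and cap
    vertices are flagged fixed (no growth anchors).

    ``center_height = 0`` clips at the equator, giving a hemisphere.
    """
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    if target_edge >= diameter / 4:
        raise ValueError(
            f"target_edge {target_edge} too large for a closed sphere of "
            f"diameter {diameter} (need target_edge < diameter/4)")
    r = diameter / 2.0
    if center_height is None:
        center_height = diameter / 6.0
    if abs(center_height) >= r:
        raise ValueError("center_height must lie strictly inside the sphere")

    # empirical mean chord length of the relaxed geodesic sphere:
    # mean_edge ~ 1.206 * r / frequency
    freq = max(2, int(np.round(1.206 * r / target_edge)))
    v, f = geodesic_sphere(r, freq)
    v = v + np.array([center_xy[0], center_xy[1], center_height])

    m = trimesh.Trimesh(v, f, process=False)
    clipped = trimesh.intersections.slice_mesh_plane(
        m, plane_normal=[0, 0, 1.0], plane_origin=[0, 0, 0.0], cap=False)
    clipped.merge_vertices(merge_tex=True, merge_norm=True)
    clipped.update_faces(clipped.nondegenerate_faces())
    cv = np.asarray(clipped.vertices, dtype=float)
    cf = np.asarray(clipped.faces, dtype=np.int64)

    rim_radius = float(np.sqrt(r * r - center_height * center_height))

    def snap_rim(s: TriSurface) -> TriSurface:
        # the sphere-plane cut is a circle; keep rim vertices exactly on it
        # so the cap triangulation sees a convex boundary
        be = s.boundary_edges()
        rim_ids = np.unique(be)
        p = s.vertices[rim_ids, :2] - np.asarray(center_xy)
        rad = np.linalg.norm(p, axis=1)
        s.vertices[rim_ids, :2] = (np.asarray(center_xy)
                                   + p * (rim_radius / rad)[:, None])
        s.vertices[rim_ids, 2] = 0.0
        return s

    surf = TriSurface(cv, cf, np.zeros(len(cv), dtype=bool))
    surf = snap_rim(surf)
    # clean the rim: slicing can create arbitrarily short edges there
    surf = _collapse_short_boundary_edges(surf, 0.5 * target_edge)
    surf = snap_rim(surf)
    cv, cf = surf.vertices, surf.faces

    # ordered rim loop
    be = surf.boundary_edges()
    rim_order = _order_loop(be)
    rim_pts = cv[rim_order]

    cap_pts, cap_tris = _fill_disk(rim_pts, target_edge)
    n_rim = len(rim_order)
    # map cap point indices into global mesh: first n_rim are rim vertices
    offset = len(cv)
    cap_map = np.concatenate([rim_order,
                              np.arange(offset, offset + len(cap_pts) - n_rim)])
    all_v = np.vstack([cv, cap_pts[n_rim:]])
    all_f = np.vstack([cf, cap_map[cap_tris]])

    fixed = np.abs(all_v[:, 2]) < _Z_TOL
    out = TriSurface(all_v, all_f, fixed)
    if not out.is_closed():
        raise RuntimeError("initial colony failed to close")
    # ensure global outward orientation
    if enclosed_volume(out) < 0:
        out.faces = out.faces[:, ::-1]
    return out


def _order_loop(edges: np.ndarray) -> np.ndarray:
    """Order boundary edges into a single closed vertex loop."""
    adj: dict[int, list[int]] = {}
    for a, b in edges:
        adj.setdefault(int(a), []).append(int(b))
        adj.setdefault(int(b), []).append(int(a))
    start = int(edges[0, 0])
    loop = [start]
    prev = None
    cur = start
    while True:
        nxt = [n for n in adj[cur] if n != prev]
        if not nxt:
            raise RuntimeError("open boundary loop")
        prev, cur = cur, nxt[0]
        if cur == start:
            break
        loop.append(cur)
    return np.array(loop, dtype=np.int64)


def _collapse_short_boundary_edges(surf: TriSurface, min_len: float
                                   ) -> TriSurface:
    """Collapse boundary (rim) edges shorter than ``min_len``."""
    while True:
        be = surf.boundary_edges()
        if len(be) == 0:
            return surf
        lens = np.linalg.norm(surf.vertices[be[:, 0]] - surf.vertices[be[:, 1]],
                              axis=1)
        short = np.argsort(lens)
        done = True
        for idx in short:
            if lens[idx] >= min_len:
                break
            a, b = int(be[idx, 0]), int(be[idx, 1])
            res = _collapse_edge(surf, a, b, midpoint=True)
            if res is None:
                continue
            surf = res
            done = False
            break
        if done:
            return surf


# ---------------------------------------------------------------------------
# normals
# ---------------------------------------------------------------------------

def vertex_normals(surface: TriSurface) -> np.ndarray:
    """Angle-weighted per-vertex outward unit normals.

    Each incident triangle contributes its unit face normal weighted by the
    corner angle at the vertex; the accumulated vector is normalized.
    Deterministic for a fixed mesh.
    """
    v, f = surface.vertices, surface.faces
    p0, p1, p2 = v[f[:, 0]], v[f[:, 1]], v[f[:, 2]]
    fn = np.cross(p1 - p0, p2 - p0)
    norm = np.linalg.norm(fn, axis=1)
    bad = norm < 1e-300
    norm[bad] = 1.0
    fn_unit = fn / norm[:, None]

    acc = np.zeros_like(v)
    for corner, (e1, e2) in enumerate([(1, 2), (2, 0), (0, 1)]):
        a = v[f[:, e1]] - v[f[:, corner]]
        b = v[f[:, e2]] - v[f[:, corner]]
        na = np.linalg.norm(a, axis=1)
        nb = np.linalg.norm(b, axis=1)
        cosang = np.einsum("ij,ij->i", a, b) / np.maximum(na * nb, 1e-300)
        ang = np.arccos(np.clip(cosang, -1.0, 1.0))
        np.add.at(acc, f[:, corner], fn_unit * ang[:, None])

    mag = np.linalg.norm(acc, axis=1)
    iso = mag < 1e-300
    if iso.any():
        raise ValueError(
            f"isolated or degenerate vertex (no normal): {np.where(iso)[0][:5]}")
    return acc / mag[:, None]


# ---------------------------------------------------------------------------
# accretion
# ---------------------------------------------------------------------------

def accrete(surface: TriSurface, layer: GrowthLayer,
            check_self_intersection: bool = False) -> TriSurface:
    """Deposit a new growth layer: v_i' = v_i + l_i * n_i.

    Fixed (substratum) vertices do not move.  Topology is unchanged;
    triangle insertion is done separately by :func:`remesh`.

    If ``check_self_intersection`` the result is tested for triangle-triangle
    intersections (the physical analogue of branch fusion, which the model
    does not support) and ``metadata['self_intersecting']`` is set.
    """
    l = np.asarray(layer.lengths, dtype=float)
    if len(l) != surface.n_vertices:
        raise ValueError("layer length does not match vertex count")
    if (l < 0).any():
        raise ValueError("negative extension lengths")
    n = vertex_normals(surface)
    disp = l[:, None] * n
    disp[surface.fixed] = 0.0
    out = surface.copy()
    out.vertices = surface.vertices + disp
    if check_self_intersection:
        out.metadata["self_intersecting"] = bool(self_intersects(out))
    return out


def self_intersects(surface: TriSurface) -> bool:
    """Triangle-triangle intersection test (uniform-grid broad phase)."""
    v, f = surface.vertices, surface.faces
    tri = v[f]
    lo = tri.min(axis=1)
    hi = tri.max(axis=1)
    cell = max(float((hi - lo).max(axis=0).mean()), 1e-12)
    inv = 1.0 / cell
    buckets: dict[tuple, list[int]] = {}
    ilo = np.floor(lo * inv).astype(np.int64)
    ihi = np.floor(hi * inv).astype(np.int64)
    for t in range(len(f)):
        for i in range(ilo[t, 0], ihi[t, 0] + 1):
            for j in range(ilo[t, 1], ihi[t, 1] + 1):
                for k in range(ilo[t, 2], ihi[t, 2] + 1):
                    buckets.setdefault((i, j, k), []).append(t)
    checked = set()
    for members in buckets.values():
        for ii in range(len(members)):
            for jj in range(ii + 1, len(members)):
                a, b = members[ii], members[jj]
                key = (a, b)
                if key in checked:
                    continue
                checked.add(key)
                fa, fb = f[a], f[b]
                if len(set(fa.tolist()) & set(fb.tolist())):
                    continue  # sharing a vertex/edge: adjacency, not fusion
                if (lo[a] > hi[b]).any() or (lo[b] > hi[a]).any():
                    continue
                if _tri_tri_intersect(tri[a], tri[b]):
                    return True
    return False


def _tri_tri_intersect(t1: np.ndarray, t2: np.ndarray) -> bool:
    """Moller-style triangle-triangle intersection predicate."""
    def signed(p, a, b, c):
        return np.dot(np.cross(b - a, c - a), p - a)

    d1 = np.array([signed(p, *t2) for p in t1])
    if (d1 > 1e-14).all() or (d1 < -1e-14).all():
        return False
    d2 = np.array([signed(p, *t1) for p in t2])
    if (d2 > 1e-14).all() or (d2 < -1e-14).all():
        return False
    # segment test: edges of each against the other's plane/face
    for (ta, tb) in ((t1, t2), (t2, t1)):
        n = np.cross(tb[1] - tb[0], tb[2] - tb[0])
        nn = np.linalg.norm(n)
        if nn < 1e-300:
            continue
        n = n / nn
        for i in range(3):
            p, q = ta[i], ta[(i + 1) % 3]
            dp = np.dot(n, p - tb[0])
            dq = np.dot(n, q - tb[0])
            if dp * dq > 0 or abs(dp - dq) < 1e-300:
                continue
            x = p + (q - p) * (dp / (dp - dq))
            # barycentric inside test
            v0, v1w = tb[1] - tb[0], tb[2] - tb[0]
            v2 = x - tb[0]
            d00 = np.dot(v0, v0); d01 = np.dot(v0, v1w)
            d11 = np.dot(v1w, v1w)
            d20 = np.dot(v2, v0); d21 = np.dot(v2, v1w)
            den = d00 * d11 - d01 * d01
            if den <= 0:
                continue
            u = (d11 * d20 - d01 * d21) / den
            w = (d00 * d21 - d01 * d20) / den
            if u >= -1e-12 and w >= -1e-12 and u + w <= 1 + 1e-12:
                return True
    return False


# ---------------------------------------------------------------------------
# remeshing
# ---------------------------------------------------------------------------

def remesh(surface: TriSurface, target_edge: float,
           max_passes: int = 10) -> TriSurface:
    """Isotropic edge maintenance: split long edges, collapse short ones.

    Edges longer than 1.5x the target are split at their midpoint (the new
    vertex interpolates all scalar channels and inherits the fixed flag only
    if both endpoints are fixed); edges shorter than 0.5x the target are
    collapsed where the collapse keeps the mesh 2-manifold.  Skipped
    collapses are counted in ``metadata['remesh_skipped']``.
    """
    surf = surface.copy()
    splits = collapses = skipped = 0
    for _ in range(max_passes):
        changed = False
        surf, ns = _split_pass(surf, 1.5 * target_edge)
        splits += ns
        surf, nc, nsk = _collapse_pass(surf, 0.5 * target_edge)
        collapses += nc
        skipped += nsk
        changed = ns > 0 or nc > 0
        if not changed:
            break
    surf.metadata.update(remesh_splits=splits, remesh_collapses=collapses,
                         remesh_skipped=skipped)
    return surf


def _split_pass(surf: TriSurface, max_len: float) -> tuple[TriSurface, int]:
    e = surf.edges_unique()
    lens = np.linalg.norm(surf.vertices[e[:, 0]] - surf.vertices[e[:, 1]],
                          axis=1)
    long_mask = lens > max_len
    if not long_mask.any():
        return surf, 0
    # split an independent set per pass: no two split edges share a face
    order = np.argsort(-lens)
    edge_to_faces = _edge_face_map(surf.faces)
    used_faces: set[int] = set()
    chosen = []
    for idx in order:
        if not long_mask[idx]:
            break
        key = (int(e[idx, 0]), int(e[idx, 1]))
        fs = edge_to_faces.get(key, [])
        if any(fi in used_faces for fi in fs):
            continue
        chosen.append((key, fs))
        used_faces.update(fs)
    if not chosen:
        return surf, 0

    v = surf.vertices
    new_v = [v]
    new_fixed = [surf.fixed]
    new_data = {k: [d] for k, d in surf.vertex_data.items()}
    faces = surf.faces.tolist()
    dead = set()
    next_id = len(v)
    add_faces = []
    for (a, b), fs in chosen:
        mid = 0.5 * (v[a] + v[b])
        fx = surf.fixed[a] and surf.fixed[b]
        if fx:
            mid[2] = 0.0
        new_v.append(mid[None, :])
        new_fixed.append(np.array([fx]))
        for k, d in surf.vertex_data.items():
            new_data[k].append(np.array([0.5 * (d[a] + d[b])]))
        m = next_id
        next_id += 1
        for fi in fs:
            tri = faces[fi]
            dead.add(fi)
            # replace edge (a,b) by two triangles through m
            c = [x for x in tri if x != a and x != b][0]
            # keep original orientation
            i_a = tri.index(a)
            if tri[(i_a + 1) % 3] == b:
                add_faces.append([a, m, c])
                add_faces.append([m, b, c])
            else:
                add_faces.append([b, m, c])
                add_faces.append([m, a, c])
    keep = [faces[i] for i in range(len(faces)) if i not in dead]
    out = TriSurface(np.vstack(new_v), np.array(keep + add_faces, dtype=np.int64),
                     np.concatenate(new_fixed),
                     {k: np.concatenate(parts) for k, parts in new_data.items()},
                     dict(surf.metadata))
    return out, len(chosen)


def _edge_face_map(faces: np.ndarray) -> dict[tuple, list[int]]:
    m: dict[tuple, list[int]] = {}
    for fi, (a, b, c) in enumerate(faces):
        for u, w in ((a, b), (b, c), (c, a)):
            key = (int(min(u, w)), int(max(u, w)))
            m.setdefault(key, []).append(fi)
    return m


def _collapse_pass(surf: TriSurface, min_len: float
                   ) -> tuple[TriSurface, int, int]:
    collapses = skipped = 0
    while True:
        e = surf.edges_unique()
        lens = np.linalg.norm(surf.vertices[e[:, 0]] - surf.vertices[e[:, 1]],
                              axis=1)
        order = np.argsort(lens)
        acted = False
        tried = 0
        for idx in order:
            if lens[idx] >= min_len or tried > 50:
                break
            a, b = int(e[idx, 0]), int(e[idx, 1])
            res = _collapse_edge(surf, a, b, midpoint=True)
            tried += 1
            if res is None:
                skipped += 1
                continue
            surf = res
            collapses += 1
            acted = True
            break
        if not acted:
            return surf, collapses, skipped


def _collapse_edge(surf: TriSurface, a: int, b: int,
                   midpoint: bool = True) -> TriSurface | None:
    """Collapse edge (a, b) into a single vertex; None if non-manifold.

    The link condition is enforced: the shared one-ring neighbours of a and
    b must be exactly the opposite vertices of the faces incident to the
    edge.  Fixed endpoints keep their position (collapse onto the fixed
    vertex); collapsing a fixed vertex into a free one is refused.
    """
    f = surf.faces
    inc_a = set(np.where((f == a).any(axis=1))[0])
    inc_b = set(np.where((f == b).any(axis=1))[0])
    shared_faces = inc_a & inc_b
    nbr_a = set(f[list(inc_a)].ravel()) - {a}
    nbr_b = set(f[list(inc_b)].ravel()) - {b}
    opposite = set(f[list(shared_faces)].ravel()) - {a, b}
    if (nbr_a & nbr_b) != opposite:
        return None
    fa, fb = surf.fixed[a], surf.fixed[b]
    if fa and not fb:
        target_pos = surf.vertices[a]
    elif fb and not fa:
        target_pos = surf.vertices[b]
    elif midpoint:
        target_pos = 0.5 * (surf.vertices[a] + surf.vertices[b])
        if fa and fb:
            target_pos = target_pos.copy()
            target_pos[2] = 0.0
    else:
        target_pos = surf.vertices[a]

    keep = np.array([i for i in range(len(f)) if i not in shared_faces])
    new_f = f[keep].copy()
    new_f[new_f == b] = a
    v = surf.vertices.copy()
    v[a] = target_pos
    fixed = surf.fixed.copy()
    fixed[a] = fa or fb
    data = {k: d.copy() for k, d in surf.vertex_data.items()}
    for k in data:
        data[k][a] = 0.5 * (data[k][a] + data[k][b])
    # drop vertex b, reindex
    mask = np.ones(len(v), dtype=bool)
    mask[b] = False
    remap = np.cumsum(mask) - 1
    new_f = remap[new_f]
    out = TriSurface(v[mask], new_f, fixed[mask],
                     {k: d[mask] for k, d in data.items()}, dict(surf.metadata))
    # reject collapses creating degenerate or duplicated faces
    tri = out.vertices[out.faces]
    areas = 0.5 * np.linalg.norm(
        np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1)
    if (areas < 1e-12 * max(1.0, areas.max())).any():
        return None
    return out


# ---------------------------------------------------------------------------
# measures
# ---------------------------------------------------------------------------

def surface_area(surface: TriSurface) -> float:
    tri = surface.vertices[surface.faces]
    return float(0.5 * np.linalg.norm(
        np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1).sum())


def enclosed_volume(surface: TriSurface) -> float:
    """Signed volume by the divergence theorem (positive = outward faces)."""
    tri = surface.vertices[surface.faces]
    return float(np.einsum("ij,ij->i", tri[:, 0],
                           np.cross(tri[:, 1], tri[:, 2])).sum() / 6.0)


def surface_area_volume(surface: TriSurface) -> tuple[float, float]:
    """(area m^2, volume m^3) of a closed surface (basal cap included)."""
    if not surface.is_closed():
        raise ValueError("surface is not closed (missing substratum cap?)")
    return surface_area(surface), abs(enclosed_volume(surface))
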