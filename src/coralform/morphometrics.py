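"""3D morphometrics of branching colonies.

Works on binary voxel volumes (CT-like) or on triangle meshes (voxelized
internally).  The pipeline mirrors the standard skeleton-based analysis of
branching marine organisms:

* topology-preserving thinning reduces the solid to a one-voxel-wide
  medial network with the same branching structure,
* the network is traced into a graph whose nodes are junctions and branch
  tips, each carrying the radius of the largest inscribed sphere
  (Euclidean distance transform in physical units, so anisotropic CT
  pitches are handled),
* terminal branch thickness dc = inscribed-sphere diameter at the tips;
  its mean is the characteristic length for the branch-scale Peclet and
  Reynolds numbers,
* symmetry angles h_angle / v_angle orient every node relative to the
  substratum plane and to the vertical plane orthogonal to the flow, and
* the symmetry magnitude sm_mag projects each node onto the upstream
  direction; a signed sum near zero means streamwise symmetry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize

from . import geometry as geo
from .flow import voxelize_mesh
from .transport import peclet_number, reynolds_number


@dataclass
class VoxelVolume:
    """Binary occupancy grid with physical pitch and origin (metres)."""

    data: np.ndarray
    pitch: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    substratum_slices: int = 0   # bottom z-slices that are support slab

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        self.pitch = tuple(float(p) for p in np.broadcast_to(
            np.asarray(self.pitch, dtype=float), (3,)))
        self.origin = tuple(float(o) for o in self.origin)

    def largest_component(self) -> "VoxelVolume":
        lab, n = ndimage.label(self.data,
                               structure=np.ones((3, 3, 3), dtype=int))
        if n <= 1:
            return self
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, range(1, n + 1))
        keep = 1 + int(np.argmax(sizes))
        return VoxelVolume(lab == keep, self.pitch, self.origin,
                           self.substratum_slices)

    def n_components(self) -> int:
        _, n = ndimage.label(self.data,
                             structure=np.ones((3, 3, 3), dtype=int))
        return int(n)

    def volume_m3(self) -> float:
        return float(self.data.sum() * np.prod(self.pitch))


@dataclass
class SkeletonGraph:
    """Medial-axis graph: junctions and tips with inscribed-sphere radii."""

    graph: nx.Graph                 # nodes: int ids with attrs pos, radius
    root: int                       # v0: node nearest the attachment point
    voxel_count: int = 0

    def positions(self) -> dict[int, np.ndarray]:
        return {n: np.asarray(d["pos"]) for n, d in self.graph.nodes(data=True)}

    def endpoints(self) -> list[int]:
        return [n for n, d in self.graph.nodes(data=True) if d["endpoint"]]

    def cycle_rank(self) -> int:
        g = self.graph
        return g.number_of_edges() - g.number_of_nodes() \
            + nx.number_connected_components(g)


# ---------------------------------------------------------------------------
# skeletonization
# ---------------------------------------------------------------------------

_NEIGH = np.array([(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1)
                   for k in (-1, 0, 1) if (i, j, k) != (0, 0, 0)])


def skeletonize_volume(volume: VoxelVolume) -> SkeletonGraph:
    """Thin the volume to a medial network and trace it into a graph.

    Topology-preserving 3D thinning (simple-point deletion); node set =
    voxels with 26-neighbour degree != 2 (tips and junctions), with
    26-adjacent junction voxels merged into single nodes.  The graph keeps
    the branching topology of the volume: same number of connected
    components, same loop count.
    """
    vol = volume
    if vol.substratum_slices > 0:
        data = vol.data[:, :, vol.substratum_slices:]
        origin = (vol.origin[0], vol.origin[1],
                  vol.origin[2] + vol.substratum_slices * vol.pitch[2])
    else:
        data = vol.data
        origin = vol.origin
    if data.sum() == 0:
        raise ValueError("empty volume")
    lab, ncomp = ndimage.label(data, structure=np.ones((3, 3, 3), dtype=int))
    if ncomp > 1:
        raise ValueError(
            f"volume has {ncomp} connected components; apply the "
            "largest-component filter first")

    # zero-pad so objects touching the border are thinned correctly
    skel = skeletonize(np.pad(data, 1))[1:-1, 1:-1, 1:-1]
    if skel.sum() == 0:
        # thinning can erase a perfectly convex blob to nothing; keep the
        # innermost voxel so downstream code sees one degenerate node
        edt = ndimage.distance_transform_edt(data, sampling=vol.pitch)
        skel = np.zeros_like(data)
        skel[np.unravel_index(np.argmax(edt), data.shape)] = True

    edt = ndimage.distance_transform_edt(data, sampling=vol.pitch)
    coords = np.argwhere(skel)
    coord_set = {tuple(c): i for i, c in enumerate(coords)}

    # 26-neighbour adjacency between skeleton voxels
    adj: list[list[int]] = [[] for _ in range(len(coords))]
    for i, c in enumerate(coords):
        for off in _NEIGH:
            nb = tuple(c + off)
            j = coord_set.get(nb)
            if j is not None and j > i:
                adj[i].append(j)
                adj[j].append(i)

    deg = np.array([len(a) for a in adj])
    node_vox = np.where(deg != 2)[0]
    if len(node_vox) == 0:
        # pure cycle: pick an arbitrary voxel as the single node
        node_vox = np.array([0])

    # merge 26-adjacent node voxels (junction clusters) into single nodes
    vox_is_node = np.zeros(len(coords), dtype=bool)
    vox_is_node[node_vox] = True
    cluster = -np.ones(len(coords), dtype=int)
    n_clusters = 0
    for i in node_vox:
        if cluster[i] >= 0:
            continue
        stack = [i]
        cluster[i] = n_clusters
        while stack:
            cur = stack.pop()
            for j in adj[cur]:
                if vox_is_node[j] and cluster[j] < 0:
                    cluster[j] = n_clusters
                    stack.append(j)
        n_clusters += 1

    pitch = np.asarray(vol.pitch)
    g = nx.Graph()
    cluster_members: list[list[int]] = [[] for _ in range(n_clusters)]
    for i in node_vox:
        cluster_members[cluster[i]].append(i)
    for cid, members in enumerate(cluster_members):
        pts = (coords[members] + 0.5) * pitch + np.asarray(origin)
        radius = float(edt[tuple(coords[members].T)].max())
        mdeg = max(int(deg[m]) for m in members)
        on_border = bool((coords[members] == 0).any() or
                         ((coords[members] + 1) == data.shape).any())
        g.add_node(cid, pos=pts.mean(axis=0), radius=radius,
                   endpoint=(mdeg <= 1), border=on_border,
                   voxel=tuple(coords[members[0]]))

    # trace paths between node clusters through degree-2 chains
    visited_edges = set()
    for cid, members in enumerate(cluster_members):
        for start in members:
            for nxt in adj[start]:
                if vox_is_node[nxt]:
                    other = cluster[nxt]
                    if other != cid:
                        key = tuple(sorted((cid, other)))
                        if key not in visited_edges:
                            visited_edges.add(key)
                            g.add_edge(cid, other, length=float(
                                np.linalg.norm((coords[start] - coords[nxt])
                                               * pitch)))
                    continue
                # walk the chain
                path = [start, nxt]
                prev, cur = start, nxt
                while not vox_is_node[cur]:
                    nbrs = [j for j in adj[cur] if j != prev]
                    if not nbrs:
                        break
                    prev, cur = cur, nbrs[0]
                    path.append(cur)
                if vox_is_node[cur]:
                    other = cluster[cur]
                    key = (tuple(sorted((cid, other))), min(path[1:-1] or [path[0]]))
                    if key not in visited_edges:
                        visited_edges.add(key)
                        seg = np.diff(coords[path] * pitch, axis=0)
                        g.add_edge(cid, other, length=float(
                            np.linalg.norm(seg, axis=1).sum()),
                            path=np.array(path))

    _fix_tip_radii(g, coords, edt, pitch)
    _simplify(g)
    if g.number_of_nodes() < 2:
        # unbranched (near-convex) colony: the medial structure collapses.
        # Represent it as a single trunk — keep the deepest node and anchor
        # the root at the attachment centroid on the substratum plane.
        base = np.argwhere(data[:, :, 0])
        if len(base):
            pos = np.append((base.mean(axis=0) + 0.5) * pitch[:2]
                            + np.asarray(origin[:2]), origin[2])
            rid = max(g.nodes) + 1 if g.number_of_nodes() else 0
            g.add_node(rid, pos=pos,
                       radius=float(edt[tuple(np.array(
                           [int(base.mean(axis=0)[0]),
                            int(base.mean(axis=0)[1]), 0]))]),
                       endpoint=False, border=True,
                       voxel=(int(base.mean(axis=0)[0]),
                              int(base.mean(axis=0)[1]), 0))
            for n in g.nodes:
                if n != rid:
                    g.add_edge(rid, n, length=float(np.linalg.norm(
                        g.nodes[n]["pos"] - pos)))
            return SkeletonGraph(graph=g, root=rid,
                                 voxel_count=int(skel.sum()))
    root = _pick_root(g, data, pitch, origin)
    return SkeletonGraph(graph=g, root=root, voxel_count=int(skel.sum()))


def _fix_tip_radii(g: nx.Graph, coords: np.ndarray, edt: np.ndarray,
                   pitch: np.ndarray) -> None:
    """Use the shaft thickness near each tip, not the cap-limited value.

    The medial axis of a flat-capped branch terminates about one radius
    short of the cap, where the inscribed sphere is still clipped by the
    cap; the inscribed-sphere radius a short way down the terminal path
    recovers the true branch thickness.
    """
    for n, d in g.nodes(data=True):
        if not d["endpoint"] or g.degree(n) == 0:
            continue
        r_tip = d["radius"]
        budget = 2.0 * r_tip + 2.0 * pitch.max()
        best = r_tip
        for _, _, ed in g.edges(n, data=True):
            path = ed.get("path")
            if path is None:
                continue
            pv = coords[path]
            # orient the walk starting at the tip end
            tip_vox = np.asarray(d["voxel"])
            if np.abs(pv[-1] - tip_vox).sum() < np.abs(pv[0] - tip_vox).sum():
                pv = pv[::-1]
            dist = np.concatenate([[0.0], np.cumsum(
                np.linalg.norm(np.diff(pv * pitch, axis=0), axis=1))])
            sel = dist <= budget
            best = max(best, float(edt[tuple(pv[sel].T)].max()))
        d["radius"] = best


def _simplify(g: nx.Graph) -> None:
    """Contract junction-junction edges shorter than the local thickness.

    Thinning a thick basal region leaves tiny internal branches between
    nearby junction voxels; a branch shorter than the radius of the
    inscribed sphere it sits in is an artefact of the medial axis, not a
    morphological branch.  Tips are never merged away.
    """
    changed = True
    while changed:
        changed = False
        for a, b, d in list(g.edges(data=True)):
            if not g.has_edge(a, b):
                continue
            na, nb = g.nodes[a], g.nodes[b]
            if na["endpoint"] or nb["endpoint"]:
                continue
            r = max(na["radius"], nb["radius"])
            if d["length"] < 1.2 * r:
                keep, drop = (a, b) if na["radius"] >= nb["radius"] else (b, a)
                kd = g.nodes[keep]
                dd = g.nodes[drop]
                kd["border"] = kd["border"] or dd["border"]
                for nbr in list(g.neighbors(drop)):
                    if nbr == keep:
                        continue
                    ln = g.edges[drop, nbr]["length"]
                    if g.has_edge(keep, nbr):
                        g.edges[keep, nbr]["length"] = min(
                            g.edges[keep, nbr]["length"], ln)
                    else:
                        g.add_edge(keep, nbr, length=ln)
                g.remove_node(drop)
                changed = True
    # degree may have changed: refresh endpoint flags for junctions that
    # lost all but one neighbour (tips keep their flag)
    for n, d in g.nodes(data=True):
        if not d["endpoint"] and g.degree(n) <= 1 and g.number_of_nodes() > 1:
            d["endpoint"] = True


def _pick_root(g: nx.Graph, data: np.ndarray, pitch: np.ndarray,
               origin) -> int:
    """Node nearest the colony-substratum attachment centroid."""
    base = np.argwhere(data[:, :, 0])
    if len(base):
        target = np.append((base.mean(axis=0) + 0.5) * pitch[:2]
                           + np.asarray(origin[:2]), origin[2])
    else:
        # free-floating object: lowest point
        low = np.argwhere(data)
        zmin = low[:, 2].min()
        sel = low[low[:, 2] == zmin]
        target = (sel.mean(axis=0) + 0.5) * pitch + np.asarray(origin)
    best, best_d = None, np.inf
    for n, d in g.nodes(data=True):
        dist = np.linalg.norm(d["pos"] - target)
        if dist < best_d:
            best, best_d = n, dist
    return best


# alias matching the operation vocabulary
skeletonize_graph = skeletonize_volume


# ---------------------------------------------------------------------------
# terminal branch thickness
# ---------------------------------------------------------------------------

def terminal_thickness(skeleton: SkeletonGraph, volume: VoxelVolume | None = None
                       ) -> tuple[np.ndarray, float]:
    """dc at each usable endpoint and the mean dc (metres).

    dc = 2 x the Euclidean distance-transform radius stored on the node
    (largest inscribed sphere at the branch tip).  Endpoints lying on the
    volume border (including the substratum cut) are flagged and excluded
    from the mean.
    """
    ends = [n for n in skeleton.endpoints()
            if not skeleton.graph.nodes[n]["border"]
            and n != skeleton.root]
    if not ends:
        raise ValueError("no terminal branches: skeleton has no usable "
                         "endpoints (degenerate, e.g. a sphere)")
    dc = np.array([2.0 * skeleton.graph.nodes[n]["radius"] for n in ends])
    return dc, float(dc.mean())


# ---------------------------------------------------------------------------
# symmetry measures
# ---------------------------------------------------------------------------

def symmetry_angles(skeleton: SkeletonGraph,
                    flow_axis=(1.0, 0.0, 0.0)
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Orientation angles of each non-root node, in degrees.

    For d = v_k - v0: h_angle is the angle between d and its projection
    onto the horizontal plane through v0 (elevation above the substratum
    plane); v_angle the angle between d and its projection onto the
    vertical plane orthogonal to the flow axis.  Both lie in [0, 90] and
    sum to 90 for vectors in the flow-vertical plane.
    """
    a = np.asarray(flow_axis, dtype=float)
    if abs(a[2]) > 1e-9:
        raise ValueError("flow axis must be horizontal (perpendicular to z)")
    a = a / np.linalg.norm(a)
    v0 = skeleton.graph.nodes[skeleton.root]["pos"]
    h_list, v_list = [], []
    for n, dat in skeleton.graph.nodes(data=True):
        if n == skeleton.root:
            continue
        d = dat["pos"] - v0
        norm = np.linalg.norm(d)
        if norm < 1e-15:
            warnings.warn(f"skeleton node {n} coincides with the root; "
                          "skipped")
            continue
        h = np.degrees(np.arcsin(np.clip(abs(d[2]) / norm, 0, 1)))
        v = np.degrees(np.arcsin(np.clip(abs(np.dot(d, a)) / norm, 0, 1)))
        h_list.append(h)
        v_list.append(v)
    return np.array(h_list), np.array(v_list)


def symmetry_magnitude(skeleton: SkeletonGraph, upstream_ref
                       ) -> tuple[np.ndarray, float, float]:
    """Scalar projections of nodes onto the upstream direction.

    ``upstream_ref`` is a reference point s placed upstream of the colony
    (or an arbitrary point under no-flow conditions); its projection s'
    onto the horizontal plane through the root defines the direction.
    Returns (per-node signed sm_k, signed mean, mean magnitude); two
    mirror-opposed nodes contribute sm values that negate each other.
    """
    v0 = skeleton.graph.nodes[skeleton.root]["pos"]
    s = np.asarray(upstream_ref, dtype=float)
    s_proj = np.array([s[0], s[1], v0[2]])
    axis = s_proj - v0
    norm = np.linalg.norm(axis)
    if norm < 1e-15:
        raise ValueError("upstream reference projects onto the root")
    axis = axis / norm
    sm = []
    for n, dat in skeleton.graph.nodes(data=True):
        if n == skeleton.root:
            continue
        d = dat["pos"] - v0
        sm.append(float(np.dot(d, axis)))
    sm = np.array(sm)
    if sm.size == 0:
        raise ValueError("skeleton has no non-root nodes")
    return sm, float(sm.mean()), float(np.abs(sm).mean())


def angle_distribution_stats(angles) -> dict:
    """Mean, t-based 95% CI, adjusted skewness and excess kurtosis."""
    from scipy import stats

    a = np.asarray(angles, dtype=float)
    if a.size < 3:
        raise ValueError("need at least 3 values")
    if np.ptp(a) == 0:
        raise ValueError("zero variance: skewness undefined")
    mean = float(a.mean())
    sem = stats.sem(a)
    tcrit = stats.t.ppf(0.975, len(a) - 1)
    return {
        "mean": mean,
        "ci95": (mean - tcrit * sem, mean + tcrit * sem),
        "skewness": float(stats.skew(a, bias=False)),
        "kurtosis": float(stats.kurtosis(a, fisher=True, bias=False)),
    }


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

@dataclass
class MorphReport:
    """Per-colony morphometric record (one Table-style row)."""

    surface_area: float
    volume: float
    sv_ratio: float
    dc: np.ndarray = field(default_factory=lambda: np.array([]))
    dc_mean: float = float("nan")
    h_angle: np.ndarray = field(default_factory=lambda: np.array([]))
    v_angle: np.ndarray = field(default_factory=lambda: np.array([]))
    sm: np.ndarray = field(default_factory=lambda: np.array([]))
    sm_signed_mean: float = float("nan")
    sm_mag_mean: float = float("nan")
    pe_branch: float = float("nan")
    re_branch: float = float("nan")
    h_stats: dict = field(default_factory=dict)
    v_stats: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        """Flat dict with Table-style column names."""
        return {
            "Surface area (m^2)": self.surface_area,
            "Volume (m^3)": self.volume,
            "Surface Volume Ratio (m^-1)": self.sv_ratio,
            "dc (m)": self.dc_mean,
            "Pe branch": self.pe_branch,
            "Re branch": self.re_branch,
            "Sm_mag_mean (m)": self.sm_mag_mean,
            "Sm_signed_mean (m)": self.sm_signed_mean,
            "h_angle_mean (deg)": float(np.mean(self.h_angle))
            if self.h_angle.size else float("nan"),
            "v_angle_mean (deg)": float(np.mean(self.v_angle))
            if self.v_angle.size else float("nan"),
        }


def sv_ratio(surface_area: float, volume: float) -> float:
    """Surface/volume compactness ratio (m^-1)."""
    if volume <= 0:
        raise ValueError("volume must be positive")
    return surface_area / volume


def mesh_to_volume(surface: geo.TriSurface, pitch: float,
                   pad: int = 3) -> VoxelVolume:
    """Voxelize a closed mesh on an isotropic grid with padding."""
    lo = surface.vertices.min(axis=0) - pad * pitch
    if surface.vertices[:, 2].min() >= -0.5 * pitch:
        lo[2] = 0.0  # substratum-clipped colony: attachment at slice 0
    hi = surface.vertices.max(axis=0) + pad * pitch
    shape = tuple(int(np.ceil((hi[i] - lo[i]) / pitch)) + 1 for i in range(3))
    data = voxelize_mesh(surface.vertices, surface.faces, shape, pitch,
                         origin=tuple(lo))
    return VoxelVolume(data, (pitch, pitch, pitch), origin=tuple(lo))


def morph_report(source, flow_speed: float = 0.0,
                 diffusivity: float = float("nan"),
                 viscosity: float = float("nan"),
                 density: float = 1000.0,
                 flow_axis=(1.0, 0.0, 0.0),
                 upstream_ref=None,
                 mesh_pitch: float | None = None) -> MorphReport:
    """Assemble the full morphometric record of a colony.

    ``source`` is a :class:`VoxelVolume` or a closed
    :class:`~coralform.geometry.TriSurface` (voxelized at ``mesh_pitch``).
    Pe_branch and Re_branch use mean dc as the characteristic length, the
    convention for branching colonies.  ``upstream_ref`` defaults to one
    unit upstream (-flow_axis) of the skeleton root.
    """
    if isinstance(source, geo.TriSurface):
        area, vol = geo.surface_area_volume(source)
        if mesh_pitch is None:
            mesh_pitch = max(float(np.median(source.edge_lengths())) * 0.75,
                             1e-6)
        volume = mesh_to_volume(source, mesh_pitch)
    else:
        volume = source
        vol = volume.volume_m3()
        area = _voxel_surface_area(volume)

    report = MorphReport(surface_area=area, volume=vol,
                         sv_ratio=sv_ratio(area, vol))
    try:
        skel = skeletonize_volume(volume.largest_component())
    except ValueError:
        return report

    try:
        report.dc, report.dc_mean = terminal_thickness(skel)
    except ValueError:
        pass
    if skel.graph.number_of_nodes() > 1:
        report.h_angle, report.v_angle = symmetry_angles(skel, flow_axis)
        if upstream_ref is None:
            v0 = skel.graph.nodes[skel.root]["pos"]
            upstream_ref = v0 - np.asarray(flow_axis, dtype=float)
        report.sm, report.sm_signed_mean, report.sm_mag_mean = \
            symmetry_magnitude(skel, upstream_ref)
        for angles, key in ((report.h_angle, "h_stats"),
                            (report.v_angle, "v_stats")):
            try:
                setattr(report, key, angle_distribution_stats(angles))
            except ValueError:
                pass
    if np.isfinite(report.dc_mean):
        if np.isfinite(diffusivity):
            report.pe_branch = peclet_number(flow_speed, report.dc_mean,
                                             diffusivity)
        if np.isfinite(viscosity):
            report.re_branch = reynolds_number(density, flow_speed,
                                               report.dc_mean, viscosity)
    return report


def _voxel_surface_area(volume: VoxelVolume) -> float:
    """Mesh the voxel volume (marching cubes) and sum triangle areas."""
    from skimage.measure import marching_cubes

    padded = np.pad(volume.data, 1).astype(float)
    verts, faces, _, _ = marching_cubes(padded, level=0.5,
                                        spacing=volume.pitch)
    tri = verts[faces]
    return float(0.5 * np.linalg.norm(
        np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1).sum())
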