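"""File I/O: meshes, voxel volumes, fields and skeleton graphs.

Meshes go through trimesh (PLY binary/ascii, OFF, STL) with per-vertex
scalar channels stored as PLY vertex properties.  Voxel volumes are
written as NRRD (tiny raw-encoding codec — no installed package provides
NRRD) or TIFF stacks; gridded fields additionally as legacy-VTK
structured-points text for slice rendering.  Skeletons go to GraphML plus
a CSV edge list.
"""

from __future__ import annotations

import csv
from pathlib import Path

import networkx as nx
import numpy as np
import trimesh

from .geometry import TriSurface
from .morphometrics import SkeletonGraph, VoxelVolume


# ---------------------------------------------------------------------------
# meshes
# ---------------------------------------------------------------------------

def save_mesh(surface: TriSurface, path: str | Path) -> None:
    """Write PLY (.ply), OFF (.off) or STL (.stl), by extension.

    PLY carries the per-vertex scalar channels (flux, conc, ...) and the
    fixed flag as vertex properties.
    """
    path = Path(path)
    if path.suffix.lower() == ".ply":
        _write_ply(path, surface)
    elif path.suffix.lower() in (".off", ".stl"):
        surface.to_trimesh().export(path)
    else:
        raise ValueError(f"unsupported mesh format: {path.suffix}")


def _write_ply(path: Path, surface: TriSurface) -> None:
    # ascii PLY with custom per-vertex scalar properties (flux, conc, ...)
    # and the fixed flag; written by hand because the installed mesh
    # library does not round-trip custom vertex properties
    keys = sorted(surface.vertex_data)
    cols = [surface.vertices[:, 0], surface.vertices[:, 1],
            surface.vertices[:, 2], surface.fixed.astype(np.uint8)]
    cols += [np.asarray(surface.vertex_data[k], dtype=float) for k in keys]
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\ncomment coralform colony mesh\n")
        fh.write(f"element vertex {surface.n_vertices}\n")
        fh.write("property double x\nproperty double y\nproperty double z\n")
        fh.write("property uchar fixed\n")
        for k in keys:
            fh.write(f"property double {k}\n")
        fh.write(f"element face {len(surface.faces)}\n")
        fh.write("property list uchar int vertex_indices\nend_header\n")
        for row in zip(*cols):
            fh.write(" ".join(
                str(int(x)) if isinstance(x, (np.uint8,)) else f"{x:.17g}"
                for x in row) + "\n")
        for tri in surface.faces:
            fh.write(f"3 {tri[0]} {tri[1]} {tri[2]}\n")


def load_mesh(path: str | Path) -> TriSurface:
    """Read PLY/OFF/STL into a TriSurface (vertex channels recovered)."""
    path = Path(path)
    if path.suffix.lower() == ".ply":
        return _read_ply(path)
    mesh = trimesh.load_mesh(str(path), process=False)
    v = np.asarray(mesh.vertices, dtype=float)
    f = np.asarray(mesh.faces, dtype=np.int64)
    return TriSurface(v, f, np.zeros(len(v), dtype=bool))


def _read_ply(path: Path) -> TriSurface:
    with open(path, "rb") as fh:
        line = fh.readline().strip()
        if line != b"ply":
            raise ValueError("not a PLY file")
        fmt = None
        n_vert = n_face = 0
        props: list[str] = []
        element = None
        while True:
            text = fh.readline().decode().strip()
            if text == "end_header":
                break
            parts = text.split()
            if parts[0] == "format":
                fmt = parts[1]
            elif parts[0] == "element":
                element = parts[1]
                if element == "vertex":
                    n_vert = int(parts[2])
                else:
                    n_face = int(parts[2])
            elif parts[0] == "property" and element == "vertex":
                props.append(parts[-1])
        if fmt != "ascii":
            mesh = trimesh.load_mesh(str(path), process=False)
            v = np.asarray(mesh.vertices, dtype=float)
            f = np.asarray(mesh.faces, dtype=np.int64)
            return TriSurface(v, f, np.zeros(len(v), dtype=bool))
        vert_rows = [fh.readline().split() for _ in range(n_vert)]
        table = np.asarray(vert_rows, dtype=float)
        face_rows = [fh.readline().split()[1:4] for _ in range(n_face)]
        faces = np.asarray(face_rows, dtype=np.int64)
    cols = {p: table[:, i] for i, p in enumerate(props)}
    v = np.column_stack([cols["x"], cols["y"], cols["z"]])
    fixed = cols.get("fixed", np.zeros(n_vert)).astype(bool)
    data = {p: cols[p] for p in props
            if p not in ("x", "y", "z", "fixed", "nx", "ny", "nz")}
    return TriSurface(v, faces, fixed, vertex_data=data)


# ---------------------------------------------------------------------------
# NRRD (raw encoding, little-endian)
# ---------------------------------------------------------------------------

_NRRD_TYPES = {"uint8": np.uint8, "float": np.float32, "double": np.float64,
               "int": np.int32, "short": np.int16, "uchar": np.uint8,
               "float32": np.float32, "float64": np.float64}


def save_nrrd(path: str | Path, data: np.ndarray,
              spacings=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0)) -> None:
    data = np.ascontiguousarray(data)
    if data.dtype == bool:
        data = data.astype(np.uint8)
    tname = {np.uint8: "uint8", np.float32: "float", np.float64: "double",
             np.int32: "int", np.int16: "short"}.get(data.dtype.type)
    if tname is None:
        data = data.astype(np.float64)
        tname = "double"
    header = [
        "NRRD0004",
        "# generated by coralform",
        f"type: {tname}",
        f"dimension: {data.ndim}",
        f"sizes: {' '.join(str(s) for s in data.shape)}",
        f"spacings: {' '.join(repr(float(s)) for s in spacings[:data.ndim])}",
        "endian: little",
        "encoding: raw",
        f"space origin: ({','.join(repr(float(o)) for o in origin[:data.ndim])})",
    ]
    with open(path, "wb") as fh:
        fh.write(("\n".join(header) + "\n\n").encode())
        fh.write(data.astype(data.dtype.newbyteorder("<"), copy=False)
                 .tobytes(order="F"))


def load_nrrd(path: str | Path) -> tuple[np.ndarray, dict]:
    with open(path, "rb") as fh:
        magic = fh.readline()
        if not magic.startswith(b"NRRD"):
            raise ValueError("not an NRRD file")
        fields: dict[str, str] = {}
        while True:
            line = fh.readline()
            if line in (b"\n", b"\r\n", b""):
                break
            text = line.decode().strip()
            if text.startswith("#") or ":" not in text:
                continue
            key, val = text.split(":", 1)
            fields[key.strip()] = val.strip()
        if fields.get("encoding", "raw") != "raw":
            raise ValueError("only raw encoding supported")
        dtype = _NRRD_TYPES[fields["type"]]
        shape = tuple(int(s) for s in fields["sizes"].split())
        raw = fh.read()
    arr = np.frombuffer(raw, dtype=np.dtype(dtype).newbyteorder("<"),
                        count=int(np.prod(shape)))
    return arr.reshape(shape, order="F").copy(), fields


def save_volume(path: str | Path, volume: VoxelVolume) -> None:
    """NRRD (.nrrd) or TIFF stack (.tif/.tiff) by extension."""
    path = Path(path)
    if path.suffix.lower() == ".nrrd":
        save_nrrd(path, volume.data.astype(np.uint8), volume.pitch,
                  volume.origin)
    elif path.suffix.lower() in (".tif", ".tiff"):
        import tifffile
        tifffile.imwrite(path, volume.data.astype(np.uint8))
    else:
        raise ValueError(f"unsupported volume format: {path.suffix}")


def load_volume(path: str | Path, pitch=None, origin=(0.0, 0.0, 0.0),
                substratum_slices: int = 0) -> VoxelVolume:
    path = Path(path)
    if path.suffix.lower() == ".nrrd":
        data, fields = load_nrrd(path)
        if pitch is None and "spacings" in fields:
            pitch = tuple(float(s) for s in fields["spacings"].split())
        if "space origin" in fields:
            origin = tuple(float(s) for s in
                           fields["space origin"].strip("()").split(","))
    elif path.suffix.lower() in (".tif", ".tiff"):
        import tifffile
        data = tifffile.imread(path)
    else:
        raise ValueError(f"unsupported volume format: {path.suffix}")
    if pitch is None:
        raise ValueError("voxel pitch required for this format")
    return VoxelVolume(data > 0, pitch, origin,
                       substratum_slices=substratum_slices)


# ---------------------------------------------------------------------------
# legacy VTK structured points (text) for field slices
# ---------------------------------------------------------------------------

def save_vtk_field(path: str | Path, name: str, field: np.ndarray,
                   pitch: float, origin=(0.0, 0.0, 0.0)) -> None:
    field = np.asarray(field, dtype=float)
    nx_, ny_, nz_ = field.shape
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\ncoralform field\nASCII\n")
        fh.write("DATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {nx_} {ny_} {nz_}\n")
        fh.write(f"ORIGIN {origin[0]} {origin[1]} {origin[2]}\n")
        fh.write(f"SPACING {pitch} {pitch} {pitch}\n")
        fh.write(f"POINT_DATA {field.size}\n")
        fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
        flat = field.transpose(2, 1, 0).ravel()
        for i in range(0, len(flat), 9):
            fh.write(" ".join(f"{x:.8g}" for x in flat[i:i + 9]) + "\n")


# ---------------------------------------------------------------------------
# skeletons
# ---------------------------------------------------------------------------

def save_skeleton(skeleton: SkeletonGraph, graphml_path: str | Path,
                  edges_csv_path: str | Path | None = None) -> None:
    g = nx.Graph()
    for n, d in skeleton.graph.nodes(data=True):
        g.add_node(n, x=float(d["pos"][0]), y=float(d["pos"][1]),
                   z=float(d["pos"][2]), radius=float(d["radius"]),
                   endpoint=bool(d["endpoint"]),
                   root=bool(n == skeleton.root))
    for a, b, d in skeleton.graph.edges(data=True):
        g.add_edge(a, b, length=float(d.get("length", 0.0)))
    nx.write_graphml(g, str(graphml_path))
    if edges_csv_path is not None:
        with open(edges_csv_path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["source", "target", "length_m"])
            for a, b, d in skeleton.graph.edges(data=True):
                w.writerow([a, b, d.get("length", 0.0)])


def save_flux_csv(path: str | Path, surface: TriSurface,
                  flux: np.ndarray) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["vertex", "x", "y", "z", "flux"])
        for i, (p, fl) in enumerate(zip(surface.vertices, flux)):
            w.writerow([i, p[0], p[1], p[2], fl])
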