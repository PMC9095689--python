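"""Surface meshes, shape vectors, and mesh file I/O.

The package works on triangulated surface meshes of segmented muscles with a
fixed anatomical frame: x = medial-lateral, y = anterior-posterior,
z = proximal-distal (+z proximal/superior); the canonical side is the right
limb, and left-limb meshes are mirrored across the sagittal plane x = 0.

Geometry travels in two equivalent representations:

* :class:`SurfaceMesh` - an (n, 3) vertex array in millimetres plus a
  triangle connectivity list; and
* :class:`ShapeVector` - the same coordinates flattened vertex-major to a
  length-3n vector (x1, y1, z1, x2, ...), the form consumed by the PCA
  shape model.

STL (ASCII and binary) is read and written through :mod:`trimesh`; the
facet soup is merged into shared vertex indices by *exact* coordinate match,
preserving first-occurrence order. PLY (ASCII) is the scalar-carrying
format: per-vertex values ride along as the standard float property
``quality``, which is how difference maps are exported.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field

import numpy as np
import trimesh

from .errors import (
    DimensionError,
    MeshFormatError,
    ParameterError,
    UnsupportedFeatureError,
)

DEFAULT_FRAME_NOTE = (
    "x: medial-lateral, y: anterior-posterior, z: proximal(+)-distal(-); right limb"
)

__all__ = [
    "SurfaceMesh",
    "ShapeVector",
    "read_mesh",
    "write_mesh",
    "read_ply_scalars",
    "mesh_to_shape_vector",
    "shape_vector_to_mesh",
    "reflect_sagittal",
]


@dataclass
class SurfaceMesh:
    """Triangulated surface: vertices in mm plus 0-based triangle indices."""

    vertices: np.ndarray
    faces: np.ndarray
    frame_note: str = DEFAULT_FRAME_NOTE

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise DimensionError("vertices must be an (n, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise DimensionError("faces must be an (f, 3) array of vertex triples")
        n = len(self.vertices)
        if n < 4:
            raise MeshFormatError(f"mesh needs at least 4 vertices, got {n}")
        if not np.isfinite(self.vertices).all():
            raise MeshFormatError("mesh contains a non-finite vertex coordinate")
        if len(self.faces) and (self.faces.min() < 0 or self.faces.max() >= n):
            raise DimensionError(
                f"face index out of range [0, {n - 1}]: "
                f"min {self.faces.min()}, max {self.faces.max()}"
            )
        degenerate = (
            (self.faces[:, 0] == self.faces[:, 1])
            | (self.faces[:, 1] == self.faces[:, 2])
            | (self.faces[:, 0] == self.faces[:, 2])
        )
        if degenerate.any():
            raise MeshFormatError(
                f"degenerate face (repeated vertex index) at row {int(np.argmax(degenerate))}"
            )

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def copy(self) -> "SurfaceMesh":
        return SurfaceMesh(self.vertices.copy(), self.faces.copy(), self.frame_note)

    def edges(self) -> np.ndarray:
        """Undirected edges as sorted index pairs, one row per face edge."""
        e = np.vstack(
            [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
        )
        return np.sort(e, axis=1)

    def is_closed(self) -> bool:
        """True when every undirected edge is shared by exactly two faces."""
        _, counts = np.unique(self.edges(), axis=0, return_counts=True)
        return bool(len(counts)) and bool((counts == 2).all())

    def signed_volume(self) -> float:
        """Signed enclosed volume (divergence theorem); positive for outward winding."""
        a = self.vertices[self.faces[:, 0]]
        b = self.vertices[self.faces[:, 1]]
        c = self.vertices[self.faces[:, 2]]
        return float(np.einsum("ij,ij->i", a, np.cross(b, c)).sum() / 6.0)

    def centroid(self) -> np.ndarray:
        """Mean of the vertices (uniform weights)."""
        return self.vertices.mean(axis=0)


@dataclass
class ShapeVector:
    """Flattened 3n coordinate vector of one corresponded specimen."""

    values: np.ndarray
    n_vertices: int = field(default=0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64).ravel()
        if self.n_vertices == 0:
            if len(self.values) % 3:
                raise DimensionError("shape vector length must be a multiple of 3")
            self.n_vertices = len(self.values) // 3
        if len(self.values) != 3 * self.n_vertices:
            raise DimensionError(
                f"shape vector has {len(self.values)} values, "
                f"expected 3 x {self.n_vertices}"
            )

    def points(self) -> np.ndarray:
        """The coordinates as an (n, 3) array (a view when possible)."""
        return self.values.reshape(self.n_vertices, 3)


def mesh_to_shape_vector(mesh: SurfaceMesh) -> ShapeVector:
    """Flatten a mesh's vertices to the vertex-major (x1, y1, z1, ...) vector."""
    return ShapeVector(mesh.vertices.reshape(-1).copy(), mesh.n_vertices)


def shape_vector_to_mesh(
    vec: ShapeVector, topology: np.ndarray, frame_note: str = DEFAULT_FRAME_NOTE
) -> SurfaceMesh:
    """Rebuild a mesh from a shape vector and a face list on the same indexing."""
    topology = np.asarray(topology, dtype=np.int64)
    if len(topology) and topology.max() >= vec.n_vertices:
        raise DimensionError(
            f"face index {int(topology.max())} out of range for "
            f"{vec.n_vertices} vertices"
        )
    return SurfaceMesh(vec.points().copy(), topology.copy(), frame_note)


def reflect_sagittal(mesh: SurfaceMesh) -> SurfaceMesh:
    """Mirror across the sagittal plane x = 0 (left limb -> right limb).

    Every x-coordinate is negated and the face winding is reversed so the
    outward orientation of the surface is preserved (the signed volume of a
    closed mesh is unchanged). Applying the operation twice returns the
    original mesh exactly.
    """
    verts = mesh.vertices * np.array([-1.0, 1.0, 1.0])
    faces = mesh.faces[:, ::-1]
    return SurfaceMesh(verts, faces, mesh.frame_note)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------


def _infer_format(path: str, fmt: str | None) -> str:
    if fmt is None:
        fmt = os.path.splitext(path)[1].lstrip(".").lower()
    fmt = fmt.lower()
    if fmt not in ("stl", "ply"):
        raise ParameterError(f"unsupported mesh format {fmt!r}; use 'stl' or 'ply'")
    return fmt


def _merge_exact(vertices: np.ndarray, faces: np.ndarray):
    """Merge duplicate vertices by exact coordinate equality.

    First-occurrence order is preserved so writing and re-reading a mesh is
    stable. No tolerance is applied: synthetic meshes are generated exactly
    and a tolerance would be a silent free parameter.
    """
    _, first, inverse = np.unique(
        vertices, axis=0, return_index=True, return_inverse=True
    )
    order = np.argsort(first)  # unique rows in first-appearance order
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))
    return vertices[np.sort(first)], rank[inverse][faces]


def read_mesh(path: str, fmt: str | None = None) -> SurfaceMesh:
    """Read an STL (ASCII or binary, auto-detected) or ASCII PLY surface mesh.

    STL facet soup is merged into shared vertex indices by exact coordinate
    match. Raises ``MeshFormatError`` on malformed geometry and ``IOError``
    when the file cannot be opened.
    """
    fmt = _infer_format(path, fmt)
    if not os.path.exists(path):
        raise IOError(f"mesh file not found: {path}")
    if fmt == "ply":
        mesh, _ = _read_ply(path)
        return mesh
    try:
        loaded = trimesh.load(path, file_type="stl", process=False)
    except Exception as exc:  # trimesh raises assorted types on bad input
        raise MeshFormatError(f"cannot parse {path} as STL: {exc}") from exc
    verts = np.asarray(loaded.vertices, dtype=np.float64)
    faces = np.asarray(loaded.faces, dtype=np.int64)
    if len(faces) == 0 or len(verts) == 0:
        raise MeshFormatError(f"{path}: empty facet list")
    if not np.isfinite(verts).all():
        bad = int(np.argwhere(~np.isfinite(verts))[0, 0])
        raise MeshFormatError(f"{path}: non-finite coordinate at vertex record {bad}")
    verts, faces = _merge_exact(verts, faces)
    return SurfaceMesh(verts, faces)


def write_mesh(
    mesh: SurfaceMesh,
    path: str,
    fmt: str | None = None,
    scalars: np.ndarray | None = None,
    stl_dialect: str = "binary",
) -> None:
    """Write a mesh as STL (geometry only) or ASCII PLY (optionally with scalars).

    ``scalars`` (PLY only) is a per-vertex float array stored as the standard
    PLY property ``quality`` - the channel used for difference maps.
    """
    fmt = _infer_format(path, fmt)
    if fmt == "stl":
        if scalars is not None:
            raise UnsupportedFeatureError(
                "STL has no per-vertex attribute channel; use PLY for scalars"
            )
        if stl_dialect not in ("binary", "ascii"):
            raise ParameterError(f"unknown STL dialect {stl_dialect!r}")
        tm = trimesh.Trimesh(mesh.vertices, mesh.faces, process=False)
        file_type = "stl" if stl_dialect == "binary" else "stl_ascii"
        data = tm.export(file_type=file_type)
        mode = "wb" if isinstance(data, bytes) else "w"
        with open(path, mode) as fh:
            fh.write(data)
        return
    _write_ply(mesh, path, scalars)


def read_ply_scalars(path: str) -> np.ndarray | None:
    """Return the per-vertex ``quality`` property of an ASCII PLY, if present."""
    _, scalars = _read_ply(path)
    return scalars


# -- minimal ASCII PLY codec (x, y, z [, quality] + triangle faces) ---------


def _write_ply(mesh: SurfaceMesh, path: str, scalars: np.ndarray | None) -> None:
    if scalars is not None:
        scalars = np.asarray(scalars, dtype=np.float64).ravel()
        if len(scalars) != mesh.n_vertices:
            raise DimensionError(
                f"scalars length {len(scalars)} != n_vertices {mesh.n_vertices}"
            )
    buf = io.StringIO()
    buf.write("ply\nformat ascii 1.0\ncomment myoshape surface mesh\n")
    buf.write(f"element vertex {mesh.n_vertices}\n")
    buf.write("property float x\nproperty float y\nproperty float z\n")
    if scalars is not None:
        buf.write("property float quality\n")
    buf.write(f"element face {len(mesh.faces)}\n")
    buf.write("property list uchar int vertex_indices\nend_header\n")
    for i, (x, y, z) in enumerate(mesh.vertices):
        row = f"{x:.9g} {y:.9g} {z:.9g}"
        if scalars is not None:
            row += f" {scalars[i]:.9g}"
        buf.write(row + "\n")
    for a, b, c in mesh.faces:
        buf.write(f"3 {a} {b} {c}\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def _read_ply(path: str):
    try:
        with open(path) as fh:
            lines = fh.read().splitlines()
    except OSError as exc:
        raise IOError(f"cannot read mesh file {path}: {exc}") from exc
    if not lines or lines[0].strip() != "ply":
        raise MeshFormatError(f"{path}: missing 'ply' magic line")
    n_vert = n_face = None
    vert_props: list[str] = []
    element = None
    header_end = None
    for k, line in enumerate(lines[1:], start=1):
        tok = line.split()
        if not tok:
            continue
        if tok[0] == "format":
            if tok[1] != "ascii":
                raise MeshFormatError(f"{path}: only ASCII PLY is supported")
        elif tok[0] == "element":
            element = tok[1]
            if element == "vertex":
                n_vert = int(tok[2])
            elif element == "face":
                n_face = int(tok[2])
        elif tok[0] == "property" and element == "vertex" and tok[1] != "list":
            vert_props.append(tok[-1])
        elif tok[0] == "end_header":
            header_end = k
            break
    if header_end is None or n_vert is None or n_face is None:
        raise MeshFormatError(f"{path}: incomplete PLY header")
    for axis in ("x", "y", "z"):
        if axis not in vert_props:
            raise MeshFormatError(f"{path}: vertex property {axis!r} missing")
    body = lines[header_end + 1 :]
    if len(body) < n_vert + n_face:
        raise MeshFormatError(f"{path}: truncated PLY body")
    try:
        vdata = np.array(
            [[float(v) for v in body[i].split()] for i in range(n_vert)]
        )
    except ValueError as exc:
        raise MeshFormatError(f"{path}: bad vertex record: {exc}") from exc
    if vdata.shape[1] != len(vert_props):
        raise MeshFormatError(f"{path}: vertex record width mismatch")
    cols = {p: vdata[:, i] for i, p in enumerate(vert_props)}
    verts = np.column_stack([cols["x"], cols["y"], cols["z"]])
    if not np.isfinite(verts).all():
        bad = int(np.argwhere(~np.isfinite(verts))[0, 0])
        raise MeshFormatError(f"{path}: non-finite coordinate at vertex {bad}")
    faces = []
    for i in range(n_face):
        tok = body[n_vert + i].split()
        if len(tok) < 4 or tok[0] != "3":
            raise MeshFormatError(f"{path}: face record {i} is not a triangle")
        faces.append([int(tok[1]), int(tok[2]), int(tok[3])])
    scalars = cols.get("quality")
    return SurfaceMesh(verts, np.array(faces, dtype=np.int64)), (
        None if scalars is None else scalars.copy()
    )
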