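"""Indexed triangle meshes: deduplication, topology reports, file I/O.

The extractor emits a triangle soup (one vertex record per triangle
corner); :func:`deduplicate` merges coincident vertices into an indexed
:class:`TriangleMesh`, and :func:`mesh_report` computes the quantities a
reconstruction comparison needs — triangle/vertex counts, surface area,
boundary edges, Euler characteristic, watertightness.

STL (binary), OBJ and PLY (ascii) are written and read through trimesh;
empty meshes are special-cased since an empty export is still a valid
file that must round-trip without error.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .marching import TriangleSoup

_FORMATS = {".stl": "stl", ".obj": "obj", ".ply": "ply"}


@dataclass
class TriangleMesh:
    """Deduplicated mesh: vertices, per-vertex unit normals, face index triples."""

    vertices: np.ndarray  # (V, 3) physical coordinates
    normals: np.ndarray  # (V, 3) unit length, or zero where unknown
    faces: np.ndarray  # (F, 3) int indices
    dropped_degenerate: int = 0

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.normals = np.asarray(self.normals, dtype=np.float64).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if len(self.faces) and (self.faces.min() < 0 or self.faces.max() >= len(self.vertices)):
            raise ValueError("face indices out of range")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_triangles(self) -> int:
        return len(self.faces)

    @classmethod
    def empty(cls) -> "TriangleMesh":
        return cls(np.zeros((0, 3)), np.zeros((0, 3)), np.zeros((0, 3), dtype=np.int64))


@dataclass(frozen=True)
class MeshReport:
    triangle_count: int
    vertex_count: int
    surface_area: float
    edge_count: int
    boundary_edge_count: int
    euler_characteristic: int
    watertight: bool
    dropped_degenerate: int

    def as_dict(self) -> dict:
        return {
            "triangle_count": self.triangle_count,
            "vertex_count": self.vertex_count,
            "surface_area": self.surface_area,
            "edge_count": self.edge_count,
            "boundary_edge_count": self.boundary_edge_count,
            "euler_characteristic": self.euler_characteristic,
            "watertight": self.watertight,
            "dropped_degenerate": self.dropped_degenerate,
        }


def deduplicate(soup: TriangleSoup, tolerance: float | None = None) -> TriangleMesh:
    """Merge coincident soup vertices into an indexed mesh.

    Vertices closer than ``tolerance`` hash to the same grid cell and the
    first-seen representative wins; normals of merged vertices are averaged
    and renormalized; face winding is preserved.  The default tolerance is
    1e-9 times the bounding-box diagonal — shared-edge vertices are
    bit-identical by construction, the tolerance only guards float noise.
    Faces that collapse onto fewer than 3 distinct vertices are dropped
    and counted.
    """
    if soup.n_triangles == 0:
        mesh = TriangleMesh.empty()
        mesh.dropped_degenerate = soup.dropped_degenerate
        return mesh
    if tolerance is not None and tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    pts = soup.triangles.reshape(-1, 3)
    if tolerance is None:
        diagonal = float(np.linalg.norm(pts.max(axis=0) - pts.min(axis=0)))
        tolerance = 1e-9 * diagonal

    key_of: dict[tuple, int] = {}
    vertices: list[np.ndarray] = []
    normal_sums: list[np.ndarray] = []
    indices = np.empty(len(pts), dtype=np.int64)
    nrms = soup.normals.reshape(-1, 3)
    for i, p in enumerate(pts):
        key = tuple(p) if tolerance == 0 else tuple(np.round(p / tolerance).astype(np.int64))
        j = key_of.get(key)
        if j is None:
            j = len(vertices)
            key_of[key] = j
            vertices.append(p)
            normal_sums.append(nrms[i].copy())
        else:
            normal_sums[j] += nrms[i]
        indices[i] = j

    normals = np.stack(normal_sums)
    lengths = np.linalg.norm(normals, axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        normals = np.where(lengths > 1e-300, normals / lengths, 0.0)
    faces = indices.reshape(-1, 3)
    distinct = (
        (faces[:, 0] != faces[:, 1])
        & (faces[:, 1] != faces[:, 2])
        & (faces[:, 0] != faces[:, 2])
    )
    dropped = soup.dropped_degenerate + int((~distinct).sum())
    return TriangleMesh(
        vertices=np.stack(vertices),
        normals=normals,
        faces=faces[distinct],
        dropped_degenerate=dropped,
    )


def mesh_to_soup(mesh: TriangleMesh) -> TriangleSoup:
    """Expand an indexed mesh back into a per-triangle soup."""
    if mesh.n_triangles == 0:
        return TriangleSoup.empty()
    return TriangleSoup(
        triangles=mesh.vertices[mesh.faces],
        normals=mesh.normals[mesh.faces],
        dropped_degenerate=mesh.dropped_degenerate,
    )


def surface_area(mesh: TriangleMesh) -> float:
    if mesh.n_triangles == 0:
        return 0.0
    tri = mesh.vertices[mesh.faces]
    cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    return float(0.5 * np.linalg.norm(cross, axis=1).sum())


def mesh_report(mesh: TriangleMesh) -> MeshReport:
    """Counts, area and topology summary of a mesh."""
    faces = mesh.faces
    edges: dict[tuple[int, int], int] = {}
    for a, b, c in faces:
        for u, v in ((a, b), (b, c), (c, a)):
            key = (int(u), int(v)) if u < v else (int(v), int(u))
            edges[key] = edges.get(key, 0) + 1
    boundary = sum(1 for n in edges.values() if n == 1)
    V, E, F = mesh.n_vertices, len(edges), mesh.n_triangles
    return MeshReport(
        triangle_count=F,
        vertex_count=V,
        surface_area=surface_area(mesh),
        edge_count=E,
        boundary_edge_count=boundary,
        euler_characteristic=V - E + F,
        watertight=(boundary == 0 and F > 0),
        dropped_degenerate=mesh.dropped_degenerate,
    )


# ---------------------------------------------------------------------------
# file I/O (trimesh-backed)


def _format_of(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        fmt = fmt.lower().replace("stl-binary", "stl").replace("ply-ascii", "ply")
        if fmt not in _FORMATS.values():
            raise ValueError(f"unknown mesh format {fmt!r}")
        return fmt
    try:
        return _FORMATS[path.suffix.lower()]
    except KeyError:
        raise ValueError(f"cannot infer mesh format from suffix {path.suffix!r}") from None


def write_mesh(mesh: TriangleMesh, path: str | Path, fmt: str | None = None) -> Path:
    """Write STL (binary), OBJ or PLY (ascii); format from suffix unless given."""
    import trimesh

    path = Path(path)
    fmt = _format_of(path, fmt)
    path.parent.mkdir(parents=True, exist_ok=True)
    if mesh.n_triangles == 0:
        _write_empty(path, fmt)
        return path
    tm = trimesh.Trimesh(
        vertices=mesh.vertices,
        faces=mesh.faces,
        vertex_normals=mesh.normals,
        process=False,
    )
    kwargs = {"encoding": "ascii"} if fmt == "ply" else {}
    data = tm.export(file_type=fmt, **kwargs)
    path.write_bytes(data if isinstance(data, bytes) else data.encode())
    return path


def _write_empty(path: Path, fmt: str) -> None:
    if fmt == "stl":
        path.write_bytes(b"\0" * 80 + struct.pack("<I", 0))
    elif fmt == "obj":
        path.write_text("# empty mesh\n")
    else:  # ply
        path.write_text(
            "ply\nformat ascii 1.0\n"
            "element vertex 0\nproperty float x\nproperty float y\nproperty float z\n"
            "element face 0\nproperty list uchar int vertex_indices\nend_header\n"
        )


def read_mesh(path: str | Path, fmt: str | None = None) -> TriangleMesh:
    """Read a mesh file back.

    STL stores a raw triangle soup, so connectivity is reconstructed by
    deduplication on read; OBJ/PLY preserve indexing as written.
    """
    import trimesh

    path = Path(path)
    fmt = _format_of(path, fmt)
    loaded = trimesh.load(str(path), file_type=fmt, process=False, force="mesh")
    vertices = np.asarray(loaded.vertices, dtype=np.float64).reshape(-1, 3)
    faces = np.asarray(loaded.faces, dtype=np.int64).reshape(-1, 3)
    if len(faces) == 0:
        return TriangleMesh.empty()
    try:
        normals = np.asarray(loaded.vertex_normals, dtype=np.float64).reshape(-1, 3)
    except Exception:  # noqa: BLE001 - normals are optional payload
        normals = np.zeros_like(vertices)
    mesh = TriangleMesh(vertices=vertices, normals=normals, faces=faces)
    if fmt == "stl":
        mesh = deduplicate(mesh_to_soup(mesh))
    return mesh
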