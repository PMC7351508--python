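"""Surface-mesh and point-cloud geometry: STL I/O, mirroring, rigid
alignment, grid-average subsampling, and enclosed-volume operations.

Meshes are triangulated surfaces in millimetres.  STL files store one
float32 vertex triple per facet corner; on read the triangle soup is
deduplicated by exact coordinate match so that shared vertices become
shared indices and topology (closedness, volume) is well defined.
"""

from __future__ import annotations

import io
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh as _trimesh
from scipy.spatial import cKDTree


class GeometryError(Exception):
    """Base class for geometry-layer failures."""


class MeshFormatError(GeometryError):
    """The file is not a parseable STL."""


class EmptyMeshError(GeometryError):
    """The solid contains no facets / no points."""


class TopologyError(GeometryError):
    """The mesh violates a topological precondition (e.g. not closed)."""


class ParameterError(GeometryError):
    """An operation parameter is out of its admissible range."""


class DegenerateGeometryError(GeometryError):
    """Input geometry is rank-deficient for the requested operation."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class TriMesh:
    """Triangulated surface: ``vertices`` (n, 3) mm and ``faces`` (m, 3) indices."""

    vertices: np.ndarray
    faces: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if self.faces.size and self.faces.max() >= len(self.vertices):
            raise TopologyError("face index exceeds vertex count")
        if self.faces.size:
            f = self.faces
            degenerate = (f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])
            if degenerate.any():
                raise TopologyError(
                    f"{int(degenerate.sum())} degenerate faces (repeated vertex index)"
                )

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def boundary_edges(self) -> np.ndarray:
        """Edges not shared by exactly two faces; empty for a closed mesh."""
        e = np.sort(
            np.concatenate([self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]),
            axis=1,
        )
        uniq, counts = np.unique(e, axis=0, return_counts=True)
        return uniq[counts != 2]

    def is_closed(self) -> bool:
        return self.faces.size > 0 and len(self.boundary_edges()) == 0

    def to_trimesh(self) -> _trimesh.Trimesh:
        return _trimesh.Trimesh(self.vertices.copy(), self.faces.copy(), process=False)

    @classmethod
    def from_trimesh(cls, mesh: _trimesh.Trimesh, name: str = "") -> "TriMesh":
        return cls(np.asarray(mesh.vertices, float), np.asarray(mesh.faces), name=name)


@dataclass
class PointCloud:
    """Unordered 3D points (mm) used as Gaussian-kernel centres."""

    points: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if not np.isfinite(self.points).all():
            raise ParameterError("point cloud contains non-finite coordinates")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)


@dataclass
class RigidTransform:
    """Proper rigid motion x -> R x + t."""

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, float).reshape(3, 3)
        self.translation = np.asarray(self.translation, float).reshape(3)
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-8):
            raise ParameterError("rotation matrix is not orthonormal")
        if np.linalg.det(self.rotation) < 0:
            raise ParameterError("rotation determinant must be +1 (no reflection)")

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, float) @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equivalent to applying ``other`` first, then ``self``."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)


# ---------------------------------------------------------------------------
# STL I/O (parsing delegated to trimesh; validation and dedup here)
# ---------------------------------------------------------------------------

def _validate_binary_stl(data: bytes, path: str) -> None:
    """Raise MeshFormatError with a byte offset for truncated binary files."""
    if len(data) < 84:
        raise MeshFormatError(
            f"{path}: binary STL needs an 80-byte header plus facet count, "
            f"file ends at byte {len(data)}"
        )
    (n_facets,) = struct.unpack("<I", data[80:84])
    expected = 84 + 50 * n_facets
    if len(data) != expected:
        raise MeshFormatError(
            f"{path}: header declares {n_facets} facets ({expected} bytes) "
            f"but file ends at byte {len(data)}"
        )


def read_stl(path) -> TriMesh:
    """Read a binary or ASCII STL file into a deduplicated :class:`TriMesh`.

    Vertices repeated across facets are merged by exact float equality
    (no tolerance welding), keeping topology deterministic.
    """
    path = Path(path)
    data = path.read_bytes()
    if len(data) == 0:
        raise MeshFormatError(f"{path}: empty file")
    looks_ascii = data.lstrip()[:5].lower() == b"solid" and b"facet" in data[:4096].lower()
    if not looks_ascii:
        _validate_binary_stl(data, str(path))
    try:
        raw = _trimesh.load(io.BytesIO(data), file_type="stl", process=False)
    except Exception as exc:  # pragma: no cover - trimesh error text varies
        raise MeshFormatError(f"{path}: unparseable STL ({exc})") from exc
    verts = np.asarray(raw.vertices, float)
    faces = np.asarray(raw.faces, np.int64)
    if len(faces) == 0:
        raise EmptyMeshError(f"{path}: solid contains no facets")
    uniq, inverse = np.unique(verts, axis=0, return_inverse=True)
    faces = np.asarray(inverse, np.int64).reshape(-1)[faces]
    # drop degenerate facets produced by exact-duplicate corners
    keep = (faces[:, 0] != faces[:, 1]) & (faces[:, 1] != faces[:, 2]) & (faces[:, 0] != faces[:, 2])
    faces = faces[keep]
    if len(faces) == 0:
        raise EmptyMeshError(f"{path}: all facets degenerate")
    return TriMesh(uniq, faces, name=path.stem)


def write_stl(mesh: TriMesh, path, mode: str = "binary") -> None:
    """Write ``mesh`` as STL. ``mode`` is ``"binary"`` (80-byte header +
    little-endian 50-byte facet records) or ``"ascii"``."""
    if mesh.n_faces == 0:
        raise EmptyMeshError("refusing to write an empty mesh")
    if mode not in ("binary", "ascii"):
        raise ParameterError(f"unknown STL mode {mode!r}")
    tm = mesh.to_trimesh()
    path = Path(path)
    if mode == "binary":
        path.write_bytes(_trimesh.exchange.stl.export_stl(tm))
    else:
        path.write_text(_trimesh.exchange.stl.export_stl_ascii(tm))


# ---------------------------------------------------------------------------
# elementary transforms
# ---------------------------------------------------------------------------

_AXIS = {"x": 0, "y": 1, "z": 2}


def mirror(mesh: TriMesh, axis: str = "x") -> TriMesh:
    """Reflect across the plane normal to ``axis`` (left/right conversion).

    Face winding is flipped so outward normals, and hence the signed
    volume, are preserved.
    """
    if axis not in _AXIS:
        raise ParameterError(f"axis must be one of x/y/z, got {axis!r}")
    verts = mesh.vertices.copy()
    verts[:, _AXIS[axis]] *= -1
    faces = mesh.faces[:, [0, 2, 1]]
    return TriMesh(verts, faces, name=mesh.name)


def grid_average_downsample(cloud: PointCloud, cell_size: float) -> PointCloud:
    """Voxel-grid subsampling: each occupied cubic cell of edge ``cell_size``
    (anchored at the cloud's minimum corner) is replaced by the centroid of
    its points."""
    if cell_size <= 0:
        raise ParameterError("cell_size must be positive")
    pts = cloud.points
    if len(pts) == 0:
        raise EmptyMeshError("cannot downsample an empty cloud")
    # lexicographic pre-sort makes the result independent of input order
    pts = pts[np.lexsort(pts.T)]
    idx = np.floor((pts - pts.min(axis=0)) / cell_size).astype(np.int64)
    cells, inverse = np.unique(idx, axis=0, return_inverse=True)
    sums = np.zeros((len(cells), 3))
    np.add.at(sums, inverse, pts)
    counts = np.bincount(inverse, minlength=len(cells)).astype(float)
    return PointCloud(sums / counts[:, None], source_id=cloud.source_id)


def center_align(cloud: PointCloud) -> PointCloud:
    """Translate so the centroid sits at the origin."""
    if len(cloud) == 0:
        raise EmptyMeshError("cannot centre an empty cloud")
    return PointCloud(cloud.points - cloud.centroid, source_id=cloud.source_id)


def _check_rank(points: np.ndarray, label: str) -> None:
    centered = points - points.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if len(points) < 4 or s[1] < 1e-9 * max(s[0], 1.0):
        raise DegenerateGeometryError(f"{label} cloud is rank-deficient (collinear or too few points)")


def _kabsch(src: np.ndarray, dst: np.ndarray) -> RigidTransform:
    """Least-squares proper rigid motion mapping src onto dst (paired points)."""
    cs, cd = src.mean(axis=0), dst.mean(axis=0)
    h = (src - cs).T @ (dst - cd)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return RigidTransform(rot, cd - rot @ cs)


def best_fit_rigid(source: PointCloud, target: PointCloud, max_iter: int = 50) -> RigidTransform:
    """Iterative-closest-point rigid alignment of ``source`` toward ``target``.

    Returns the transform achieving the smallest mean closest-point
    distance seen across iterations, so the alignment error is never
    worse than the initial pose.
    """
    if len(source) < 4 or len(target) < 4:
        raise DegenerateGeometryError("both clouds need at least 4 points")
    _check_rank(source.points, "source")
    _check_rank(target.points, "target")
    tree = cKDTree(target.points)
    current = RigidTransform()
    best = current
    best_err = float(np.mean(tree.query(source.points)[0]))
    prev_err = np.inf
    for _ in range(max_iter):
        moved = current.apply(source.points)
        dists, nn = tree.query(moved)
        err = float(np.mean(dists))
        if err < best_err:
            best, best_err = current, err
        if prev_err - err < 1e-12:
            break
        prev_err = err
        step = _kabsch(moved, target.points[nn])
        current = step.compose(current)
    # evaluate the final candidate as well
    final_err = float(np.mean(tree.query(current.apply(source.points))[0]))
    if final_err < best_err:
        best = current
    return best


# ---------------------------------------------------------------------------
# volume
# ---------------------------------------------------------------------------

def mesh_volume(mesh: TriMesh) -> float:
    """Enclosed volume (mm³) by the signed-tetrahedron (divergence) sum.

    Requires a closed, consistently oriented mesh; the magnitude is
    returned so orientation conventions do not flip the sign.
    """
    boundary = mesh.boundary_edges()
    if len(boundary) > 0:
        shown = ", ".join(f"({a},{b})" for a, b in boundary[:8])
        raise TopologyError(
            f"mesh is not closed: {len(boundary)} boundary/odd edges, e.g. {shown}"
        )
    v = mesh.vertices
    a, b, c = v[mesh.faces[:, 0]], v[mesh.faces[:, 1]], v[mesh.faces[:, 2]]
    signed = np.einsum("ij,ij->i", a, np.cross(b, c)).sum() / 6.0
    return float(abs(signed))


def scale_to_volume(mesh: TriMesh, target_volume: float) -> TriMesh:
    """Uniformly scale about the vertex centroid so the enclosed volume
    equals ``target_volume`` (size removal before shape comparison)."""
    if target_volume <= 0:
        raise ParameterError("target_volume must be positive")
    current = mesh_volume(mesh)
    if current <= 0:
        raise ParameterError("mesh has zero volume")
    factor = (target_volume / current) ** (1.0 / 3.0)
    centroid = mesh.vertices.mean(axis=0)
    verts = centroid + factor * (mesh.vertices - centroid)
    return TriMesh(verts, mesh.faces.copy(), name=mesh.name)
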