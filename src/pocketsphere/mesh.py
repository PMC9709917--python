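"""Triangulated surface meshes: container, cleanup, Laplacian smoothing, I/O."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import trimesh

__all__ = ["SurfaceMesh", "clean_mesh", "smooth_mesh", "write_mesh", "read_mesh"]


@dataclass
class SurfaceMesh:
    """Triangle mesh with derived unit normals.

    ``vertices`` (n, 3) Angstrom; ``faces`` (m, 3) vertex indices, oriented
    consistently outward (away from the enclosed interior).
    """

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def face_areas(self) -> np.ndarray:
        a, b, c = (self.vertices[self.faces[:, i]] for i in range(3))
        return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)

    @property
    def area(self) -> float:
        return float(self.face_areas.sum())

    @property
    def face_normals(self) -> np.ndarray:
        a, b, c = (self.vertices[self.faces[:, i]] for i in range(3))
        n = np.cross(b - a, c - a)
        norms = np.linalg.norm(n, axis=1, keepdims=True)
        return n / np.where(norms == 0, 1.0, norms)

    @property
    def vertex_normals(self) -> np.ndarray:
        """Area-weighted average of incident face normals, unit length."""
        a, b, c = (self.vertices[self.faces[:, i]] for i in range(3))
        fn = np.cross(b - a, c - a)  # area-weighted (norm = 2*area)
        vn = np.zeros_like(self.vertices)
        for i in range(3):
            np.add.at(vn, self.faces[:, i], fn)
        norms = np.linalg.norm(vn, axis=1, keepdims=True)
        return vn / np.where(norms == 0, 1.0, norms)

    def transformed(self, rotation: np.ndarray, translation=(0.0, 0.0, 0.0)) -> "SurfaceMesh":
        return SurfaceMesh(
            self.vertices @ np.asarray(rotation, float).T + np.asarray(translation, float),
            self.faces.copy(),
        )

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices, self.faces, process=False)


def clean_mesh(mesh: SurfaceMesh) -> SurfaceMesh:
    """Remove non-finite vertices, degenerate and duplicate faces, and
    unreferenced vertices.  Surviving vertex order is preserved; the
    operation is idempotent."""
    v, f = mesh.vertices, mesh.faces

    finite_v = np.all(np.isfinite(v), axis=1)
    ok = finite_v[f].all(axis=1)
    # degenerate: repeated vertex indices or zero area
    ok &= (f[:, 0] != f[:, 1]) & (f[:, 1] != f[:, 2]) & (f[:, 0] != f[:, 2])
    a, b, c = v[f[:, 0]], v[f[:, 1]], v[f[:, 2]]
    with np.errstate(invalid="ignore"):
        area2 = np.linalg.norm(np.cross(b - a, c - a), axis=1)
    ok &= np.nan_to_num(area2) > 0
    f = f[ok]

    # duplicate faces: same vertex triple in any winding; keep first occurrence
    key = np.sort(f, axis=1)
    _, first = np.unique(key, axis=0, return_index=True)
    f = f[np.sort(first)]

    # drop unreferenced vertices, preserving order of survivors
    used = np.zeros(len(v), dtype=bool)
    used[f] = True
    remap = np.cumsum(used) - 1
    v = v[used]
    f = remap[f]

    if len(f) == 0:
        raise ValueError("mesh empty after cleaning")
    return SurfaceMesh(v, f)


def _uniform_adjacency(mesh: SurfaceMesh) -> sp.csr_matrix:
    f = mesh.faces
    i = np.concatenate([f[:, 0], f[:, 1], f[:, 1], f[:, 2], f[:, 2], f[:, 0]])
    j = np.concatenate([f[:, 1], f[:, 0], f[:, 2], f[:, 1], f[:, 0], f[:, 2]])
    data = np.ones(len(i))
    adj = sp.coo_matrix((data, (i, j)), shape=(mesh.n_vertices,) * 2).tocsr()
    adj.data[:] = 1.0  # collapse duplicate edge entries
    adj.sum_duplicates()
    adj.data[:] = 1.0
    return adj


def smooth_mesh(mesh: SurfaceMesh, iterations: int = 4) -> SurfaceMesh:
    """Uniform (umbrella-weight) Laplacian smoothing.

    Each iteration replaces every vertex by the arithmetic mean of its 1-ring
    neighbors; connectivity is unchanged.  ``iterations=0`` is the identity.
    """
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    v = mesh.vertices.copy()
    if iterations == 0:
        return SurfaceMesh(v, mesh.faces.copy())
    adj = _uniform_adjacency(mesh)
    deg = np.asarray(adj.sum(axis=1)).ravel()
    deg_safe = np.where(deg == 0, 1.0, deg)
    for _ in range(iterations):
        mean = adj @ v / deg_safe[:, None]
        v = np.where(deg[:, None] > 0, mean, v)
    return SurfaceMesh(v, mesh.faces.copy())


def write_mesh(mesh: SurfaceMesh, path) -> None:
    """Export as PLY (binary little-endian) or OFF, by file extension."""
    tm = mesh.as_trimesh()
    path = str(path)
    if path.lower().endswith(".ply"):
        tm.export(path, file_type="ply", encoding="binary")
    elif path.lower().endswith(".off"):
        tm.export(path, file_type="off")
    else:
        raise ValueError("unsupported mesh format (use .ply or .off)")


def read_mesh(path) -> SurfaceMesh:
    tm = trimesh.load_mesh(str(path), process=False)
    return SurfaceMesh(np.asarray(tm.vertices, float), np.asarray(tm.faces, np.int64))
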