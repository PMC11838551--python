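"""Triangle-mesh containers and geometry kernels.

Meshes live in physical coordinates (micrometres, ``(x, y, z)`` order).
The surface of interest is a polygonal mesh ``(V, T)``; when a cartographic
unwrapping is attached, UV vertices live in the unit square and UV faces are
in one-to-one correspondence with the 3D faces (so a face may reference
different UV corners on either side of a seam while the 3D mesh stays
watertight).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

DEGENERATE_AREA = 1e-12  # μm²; faces below this are considered degenerate


@dataclass
class TriangleMesh:
    """Triangle mesh in physical (μm) coordinates.

    Parameters
    ----------
    vertices : (N, 3) float array
        Vertex positions in μm.
    faces : (M, 3) int array
        Vertex index triples; consistent counter-clockwise winding seen
        from outside for closed, outward-oriented surfaces.
    vertex_normals : (N, 3) float array, optional
        Unit outward normals. Computed on demand (angle-weighted) if absent.
    """

    vertices: np.ndarray
    faces: np.ndarray
    vertex_normals: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (N, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be (M, 3)")
        if len(self.faces) and (
            self.faces.min() < 0 or self.faces.max() >= len(self.vertices)
        ):
            raise ValueError("face indices out of range")
        if self.vertex_normals is not None:
            self.vertex_normals = np.ascontiguousarray(
                self.vertex_normals, dtype=np.float64
            )
            norms = np.linalg.norm(self.vertex_normals, axis=1)
            if np.any(np.abs(norms - 1.0) > 1e-6):
                raise ValueError("vertex normals must be unit length")

    # -- derived geometry -------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def triangle_corners(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        v = self.vertices
        f = self.faces
        return v[f[:, 0]], v[f[:, 1]], v[f[:, 2]]

    def face_areas(self) -> np.ndarray:
        a, b, c = self.triangle_corners()
        return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)

    def face_normals(self) -> np.ndarray:
        a, b, c = self.triangle_corners()
        n = np.cross(b - a, c - a)
        norm = np.linalg.norm(n, axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        return n / norm

    def face_centroids(self) -> np.ndarray:
        a, b, c = self.triangle_corners()
        return (a + b + c) / 3.0

    def area(self) -> float:
        return float(self.face_areas().sum())

    def signed_volume(self) -> float:
        """Divergence-theorem volume; positive for outward orientation."""
        a, b, c = self.triangle_corners()
        return float(np.einsum("ij,ij->i", a, np.cross(b, c)).sum() / 6.0)

    def edges(self, unique: bool = True) -> np.ndarray:
        e = np.concatenate(
            [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
        )
        if unique:
            e = np.unique(np.sort(e, axis=1), axis=0)
        return e

    def euler_characteristic(self) -> int:
        return self.n_vertices - len(self.edges()) + self.n_faces

    def edge_face_count(self) -> dict[tuple[int, int], int]:
        e = np.sort(
            np.concatenate(
                [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
            ),
            axis=1,
        )
        uniq, counts = np.unique(e, axis=0, return_counts=True)
        return {tuple(edge): int(c) for edge, c in zip(uniq, counts)}

    def is_watertight(self) -> bool:
        """Every edge shared by exactly two faces."""
        e = np.sort(
            np.concatenate(
                [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
            ),
            axis=1,
        )
        _, counts = np.unique(e, axis=0, return_counts=True)
        return bool(np.all(counts == 2))

    def boundary_edges(self) -> np.ndarray:
        """Directed boundary edges, in face winding order (surface on the left)."""
        directed = np.concatenate(
            [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
        )
        key = np.sort(directed, axis=1)
        uniq, inv, counts = np.unique(
            key, axis=0, return_inverse=True, return_counts=True
        )
        return directed[counts[inv] == 1]

    def compute_vertex_normals(self) -> np.ndarray:
        """Angle-weighted vertex normals (unit length)."""
        a, b, c = self.triangle_corners()
        fn = np.cross(b - a, c - a)  # area-weighted
        corners = (a, b, c)
        normals = np.zeros_like(self.vertices)
        for i in range(3):
            p = corners[i]
            q = corners[(i + 1) % 3] - p
            r = corners[(i + 2) % 3] - p
            qn = np.linalg.norm(q, axis=1)
            rn = np.linalg.norm(r, axis=1)
            ok = (qn > 0) & (rn > 0)
            cosang = np.zeros(len(p))
            cosang[ok] = np.clip(
                np.einsum("ij,ij->i", q[ok], r[ok]) / (qn[ok] * rn[ok]), -1, 1
            )
            ang = np.arccos(cosang)
            fnn = np.linalg.norm(fn, axis=1, keepdims=True)
            unit_fn = np.divide(fn, fnn, out=np.zeros_like(fn), where=fnn > 0)
            np.add.at(normals, self.faces[:, i], ang[:, None] * unit_fn)
        norm = np.linalg.norm(normals, axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        return normals / norm

    def ensure_vertex_normals(self) -> np.ndarray:
        if self.vertex_normals is None:
            self.vertex_normals = self.compute_vertex_normals()
        return self.vertex_normals

    def copy(self) -> "TriangleMesh":
        return dataclasses.replace(
            self,
            vertices=self.vertices.copy(),
            faces=self.faces.copy(),
            vertex_normals=None
            if self.vertex_normals is None
            else self.vertex_normals.copy(),
        )

    def validate(self) -> None:
        """Raise if the mesh violates its invariants."""
        if not np.all(np.isfinite(self.vertices)):
            raise ValueError("non-finite vertex coordinates")
        if np.any(self.face_areas() < DEGENERATE_AREA):
            raise ValueError("degenerate (zero-area) faces present")


@dataclass
class TriangleMeshUV(TriangleMesh):
    """Triangle mesh with a cartographic UV map.

    ``uv_vertices`` are 2D points in the unit square; ``uv_faces`` index into
    them and correspond one-to-one (same order, same corner order) with the
    3D ``faces``.
    """

    uv_vertices: np.ndarray = field(default_factory=lambda: np.zeros((0, 2)))
    uv_faces: np.ndarray = field(default_factory=lambda: np.zeros((0, 3), int))

    def __post_init__(self) -> None:
        super().__post_init__()
        self.uv_vertices = np.ascontiguousarray(self.uv_vertices, dtype=np.float64)
        self.uv_faces = np.ascontiguousarray(self.uv_faces, dtype=np.int64)

    def uv_face_corners(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        uv = self.uv_vertices
        f = self.uv_faces
        return uv[f[:, 0]], uv[f[:, 1]], uv[f[:, 2]]

    def uv_signed_areas(self) -> np.ndarray:
        a, b, c = self.uv_face_corners()
        return 0.5 * (
            (b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1])
            - (c[:, 0] - a[:, 0]) * (b[:, 1] - a[:, 1])
        )

    def validate_uv(self) -> None:
        if len(self.uv_faces) != len(self.faces):
            raise ValueError("uv_faces must correspond one-to-one with faces")
        if len(self.uv_vertices) and (
            self.uv_vertices.min() < -1e-9 or self.uv_vertices.max() > 1 + 1e-9
        ):
            raise ValueError("UV coordinates must lie in the unit square")
        if np.any(np.abs(self.uv_signed_areas()) < 1e-15):
            raise ValueError("zero-area UV faces present")

    def copy(self) -> "TriangleMeshUV":
        return TriangleMeshUV(
            vertices=self.vertices.copy(),
            faces=self.faces.copy(),
            vertex_normals=None
            if self.vertex_normals is None
            else self.vertex_normals.copy(),
            uv_vertices=self.uv_vertices.copy(),
            uv_faces=self.uv_faces.copy(),
        )

    def with_vertices(self, vertices: np.ndarray) -> "TriangleMeshUV":
        """Same connectivity and UV map, new 3D vertex positions."""
        return TriangleMeshUV(
            vertices=np.asarray(vertices, float).copy(),
            faces=self.faces.copy(),
            uv_vertices=self.uv_vertices.copy(),
            uv_faces=self.uv_faces.copy(),
        )


def attach_uv(
    mesh: TriangleMesh,
    uv_vertices: np.ndarray,
    uv_faces: np.ndarray,
    strict: bool = True,
) -> TriangleMeshUV:
    """Attach a UV layer to a mesh, validating the UV invariants.

    ``strict=False`` downgrades zero-area UV faces (unavoidable chart
    degeneracies, e.g. pole slivers of noisy meshes) to a warning; the
    correspondence and unit-square checks always apply.
    """
    out = TriangleMeshUV(
        vertices=mesh.vertices,
        faces=mesh.faces,
        vertex_normals=mesh.vertex_normals,
        uv_vertices=uv_vertices,
        uv_faces=uv_faces,
    )
    try:
        out.validate_uv()
    except ValueError as exc:
        if strict or "zero-area" not in str(exc):
            raise
        import warnings

        n_bad = int((np.abs(out.uv_signed_areas()) < 1e-15).sum())
        warnings.warn(
            f"{n_bad} zero-area UV face(s) in the chart (e.g. pole slivers); "
            "they cover no pullback pixels",
            stacklevel=2,
        )
    return out


# -- connectivity ---------------------------------------------------------


def face_adjacency_components(faces: np.ndarray) -> np.ndarray:
    """Label faces by edge-connected component."""
    m = len(faces)
    e = np.sort(
        np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]]), axis=1
    )
    fid = np.tile(np.arange(m), 3)
    order = np.lexsort((e[:, 1], e[:, 0]))
    e_sorted, fid_sorted = e[order], fid[order]
    same = np.all(e_sorted[1:] == e_sorted[:-1], axis=1)
    rows = fid_sorted[:-1][same]
    cols = fid_sorted[1:][same]
    adj = sp.coo_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(m, m)
    )
    _, labels = connected_components(adj, directed=False)
    return labels


def largest_component(mesh: TriangleMesh) -> TriangleMesh:
    """Keep only the largest edge-connected face component."""
    if mesh.n_faces == 0:
        return mesh
    labels = face_adjacency_components(mesh.faces)
    keep = labels == np.bincount(labels).argmax()
    return remove_unused_vertices(mesh.vertices, mesh.faces[keep])


def remove_unused_vertices(vertices: np.ndarray, faces: np.ndarray) -> TriangleMesh:
    used = np.unique(faces)
    remap = -np.ones(len(vertices), dtype=np.int64)
    remap[used] = np.arange(len(used))
    return TriangleMesh(vertices=vertices[used], faces=remap[faces])


def remove_degenerate_faces(mesh: TriangleMesh, tol: float = DEGENERATE_AREA) -> TriangleMesh:
    keep = mesh.face_areas() >= tol
    return remove_unused_vertices(mesh.vertices, mesh.faces[keep])


# -- smoothing ------------------------------------------------------------


def _uniform_adjacency(mesh: TriangleMesh) -> sp.csr_matrix:
    e = mesh.edges()
    n = mesh.n_vertices
    data = np.ones(2 * len(e))
    rows = np.concatenate([e[:, 0], e[:, 1]])
    cols = np.concatenate([e[:, 1], e[:, 0]])
    return sp.coo_matrix((data, (rows, cols)), shape=(n, n)).tocsr()


def taubin_smooth(
    mesh: TriangleMesh, iterations: int, lam: float = 0.5, mu: float = -0.53
) -> TriangleMesh:
    """Taubin λ|μ smoothing (uniform weights); ``mu=0`` gives pure Laplacian.

    The λ/μ pair alternates shrink/inflate steps so that repeated smoothing
    removes high-frequency noise without the global shrinkage of pure
    Laplacian smoothing. Connectivity is unchanged; ``iterations=0`` is the
    identity.
    """
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    out = mesh.copy()
    if iterations == 0 or mesh.n_faces == 0:
        return out
    adj = _uniform_adjacency(mesh)
    deg = np.asarray(adj.sum(axis=1)).ravel()
    deg[deg == 0] = 1.0
    v = out.vertices
    for _ in range(iterations):
        for factor in (lam, mu):
            if factor == 0:
                continue
            delta = adj @ v / deg[:, None] - v
            v = v + factor * delta
    out.vertices = v
    out.vertex_normals = None
    return out


# -- FEM operators --------------------------------------------------------


def cotangent_laplacian(mesh: TriangleMesh, clamp: bool = False) -> sp.csr_matrix:
    """Cotangent-weight Laplacian (negative semidefinite convention).

    ``L[i, j] = w_ij >= 0`` off-diagonal, ``L[i, i] = -sum_j w_ij``, with
    ``w_ij = (cot α + cot β) / 2``. ``clamp`` truncates negative cotangent
    weights at zero (Tutte-style), guaranteeing a maximum principle for
    harmonic solves on meshes with obtuse triangles.
    """
    n = mesh.n_vertices
    f = mesh.faces
    v = mesh.vertices
    rows, cols, vals = [], [], []
    for i in range(3):
        i0, i1, i2 = f[:, i], f[:, (i + 1) % 3], f[:, (i + 2) % 3]
        # angle at i0 is opposite edge (i1, i2)
        u = v[i1] - v[i0]
        w = v[i2] - v[i0]
        cross = np.linalg.norm(np.cross(u, w), axis=1)
        cross[cross == 0] = np.inf
        cot = np.einsum("ij,ij->i", u, w) / cross
        if clamp:
            cot = np.maximum(cot, 0.0)
        half = 0.5 * cot
        rows += [i1, i2]
        cols += [i2, i1]
        vals += [half, half]
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    vals = np.concatenate(vals)
    W = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    return (W - sp.diags(np.asarray(W.sum(axis=1)).ravel())).tocsr()


def lumped_mass(mesh: TriangleMesh) -> np.ndarray:
    """Barycentric lumped vertex masses (one third of incident face areas)."""
    areas = mesh.face_areas()
    m = np.zeros(mesh.n_vertices)
    for i in range(3):
        np.add.at(m, mesh.faces[:, i], areas / 3.0)
    return m


def vertex_areas(mesh: TriangleMesh) -> np.ndarray:
    return lumped_mass(mesh)
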