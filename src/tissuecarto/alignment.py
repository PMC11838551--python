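"""Surface-to-surface alignment and UV transfer across time series.

A UV-carrying reference mesh is mapped onto target meshes by rigid-body
(similarity) ICP, shrink-wrapping (closest-point projection interleaved with
smoothing), or Möbius alignment (conformal maps to the unit sphere matched
up to a sphere rotation). All aligners deform only the 3D vertices — the UV
map is carried over bit-identically, which is what makes the transferred
cartographic layout coherent across frames. For dynamic datasets the
transfer proceeds iteratively outward from a reference frame.

None of the aligners is stochastic; the Möbius rotation search uses a
deterministic quasi-uniform set of rotations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .mesh import TriangleMesh, TriangleMeshUV, lumped_mass, taubin_smooth
from .unwrap import conformal_sphere_map
from .volume import VolumetricImage


@dataclass
class SimilarityTransform:
    """p ↦ scale · R @ p + translation, with R a proper rotation."""

    rotation: np.ndarray
    scale: float = 1.0
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    residual_history: list = field(default_factory=list, compare=False)
    converged: bool = True

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, float).reshape(3, 3)
        self.translation = np.asarray(self.translation, float).reshape(3)
        if self.scale <= 0:
            raise ValueError("scale must be > 0")
        if np.abs(self.rotation @ self.rotation.T - np.eye(3)).max() > 1e-9:
            raise ValueError("rotation must be orthonormal")
        if np.linalg.det(self.rotation) < 0:
            raise ValueError("rotation must be proper (det +1)")

    @classmethod
    def identity(cls) -> "SimilarityTransform":
        return cls(rotation=np.eye(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return self.scale * points @ self.rotation.T + self.translation


def procrustes(
    ref_points: np.ndarray, target_points: np.ndarray, allow_scale: bool = True
) -> SimilarityTransform:
    """Least-squares similarity (Kabsch–Umeyama) mapping ref → target.

    Minimizes Σ‖s·R·p + t − q‖² over proper rotations R (no reflections),
    scale s (optional) and translation t.
    """
    p = np.asarray(ref_points, float)
    q = np.asarray(target_points, float)
    if p.shape != q.shape or p.ndim != 2 or p.shape[1] != 3:
        raise ValueError("point sets must both be (N, 3)")
    if len(p) < 3:
        raise ValueError("need at least 3 points")
    mp, mq = p.mean(axis=0), q.mean(axis=0)
    pc, qc = p - mp, q - mq
    cov = qc.T @ pc / len(p)
    U, S, Vt = np.linalg.svd(cov)
    if S[1] < 1e-12 * max(S[0], 1e-300):
        raise ValueError("degenerate (collinear) point configuration")
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, d])
    R = U @ D @ Vt
    if allow_scale:
        var_p = (pc**2).sum() / len(p)
        s = float((S * np.diag(D)).sum() / var_p)
    else:
        s = 1.0
    t = mq - s * R @ mp
    return SimilarityTransform(rotation=R, scale=s, translation=t)


# -- closest point on surface --------------------------------------------


def _closest_point_triangles(
    p: np.ndarray, a: np.ndarray, b: np.ndarray, c: np.ndarray
) -> np.ndarray:
    """Closest point on each triangle (a, b, c) to each query p (vectorized,
    Ericson's region test)."""
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    result = np.empty_like(p)
    done = np.zeros(len(p), bool)

    m = (d1 <= 0) & (d2 <= 0)
    result[m] = a[m]
    done |= m

    m = ~done & (d3 >= 0) & (d4 <= d3)
    result[m] = b[m]
    done |= m

    vc = d1 * d4 - d3 * d2
    m = ~done & (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        v = d1 / (d1 - d3)
    result[m] = a[m] + v[m, None] * ab[m]
    done |= m

    m = ~done & (d6 >= 0) & (d5 <= d6)
    result[m] = c[m]
    done |= m

    vb = d5 * d2 - d1 * d6
    m = ~done & (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        w = d2 / (d2 - d6)
    result[m] = a[m] + w[m, None] * ac[m]
    done |= m

    va = d3 * d6 - d5 * d4
    m = ~done & (va <= 0) & ((d4 - d3) >= 0) & ((d5 - d6) >= 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        w = (d4 - d3) / ((d4 - d3) + (d5 - d6))
    result[m] = b[m] + w[m, None] * (c[m] - b[m])
    done |= m

    m = ~done
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = va + vb + vc
        v = vb / denom
        w = vc / denom
    result[m] = a[m] + v[m, None] * ab[m] + w[m, None] * ac[m]
    return result


class SurfaceProximity:
    """Closest-point queries against a triangle mesh (cKDTree-pruned exact
    point-to-triangle minimization)."""

    def __init__(self, mesh: TriangleMesh, n_candidates: int = 12):
        self.mesh = mesh
        self.n_candidates = min(n_candidates, mesh.n_faces)
        self._centroid_tree = cKDTree(mesh.face_centroids())
        self._vertex_tree = cKDTree(mesh.vertices)
        # faces incident to each vertex, padded
        n = mesh.n_vertices
        lists: list[list[int]] = [[] for _ in range(n)]
        for fi, f in enumerate(mesh.faces):
            for v in f:
                lists[v].append(fi)
        width = max(len(l) for l in lists)
        self._vert_faces = -np.ones((n, width), dtype=np.int64)
        for v, l in enumerate(lists):
            self._vert_faces[v, : len(l)] = l

    def query(self, points: np.ndarray):
        """Return (closest points, face indices, barycentric weights)."""
        pts = np.atleast_2d(np.asarray(points, float))
        _, cand = self._centroid_tree.query(pts, k=self.n_candidates)
        cand = np.atleast_2d(cand)
        _, nearest_v = self._vertex_tree.query(pts)
        vert_cand = self._vert_faces[np.atleast_1d(nearest_v)]
        cand = np.concatenate([cand, vert_cand], axis=1)
        P, K = cand.shape
        flat_faces = cand.ravel()
        ok = flat_faces >= 0
        flat_faces_safe = np.where(ok, flat_faces, 0)
        tri = self.mesh.faces[flat_faces_safe]
        a = self.mesh.vertices[tri[:, 0]]
        b = self.mesh.vertices[tri[:, 1]]
        c = self.mesh.vertices[tri[:, 2]]
        q = np.repeat(pts, K, axis=0)
        cp = _closest_point_triangles(q, a, b, c)
        d2 = ((cp - q) ** 2).sum(axis=1)
        d2[~ok] = np.inf
        d2 = d2.reshape(P, K)
        best = d2.argmin(axis=1)
        rows = np.arange(P)
        best_face = cand[rows, best]
        best_cp = cp.reshape(P, K, 3)[rows, best]
        # barycentric weights of the closest point
        tri = self.mesh.faces[best_face]
        a = self.mesh.vertices[tri[:, 0]]
        b = self.mesh.vertices[tri[:, 1]]
        c = self.mesh.vertices[tri[:, 2]]
        bary = _barycentric_3d(best_cp, a, b, c)
        return best_cp, best_face, bary


def _barycentric_3d(p, a, b, c):
    v0 = b - a
    v1 = c - a
    v2 = p - a
    d00 = np.einsum("ij,ij->i", v0, v0)
    d01 = np.einsum("ij,ij->i", v0, v1)
    d11 = np.einsum("ij,ij->i", v1, v1)
    d20 = np.einsum("ij,ij->i", v2, v0)
    d21 = np.einsum("ij,ij->i", v2, v1)
    denom = d00 * d11 - d01 * d01
    denom[denom == 0] = np.inf
    v = (d11 * d20 - d01 * d21) / denom
    w = (d00 * d21 - d01 * d20) / denom
    return np.stack([1 - v - w, v, w], axis=-1)


def closest_point_on_surface(mesh: TriangleMesh, query: np.ndarray):
    """Closest surface point to ``query``: (point, face index, barycentric).

    Accepts a single (3,) point or an (N, 3) array. Distance is unsigned.
    """
    single = np.asarray(query).ndim == 1
    cp, face, bary = SurfaceProximity(mesh).query(query)
    if single:
        return cp[0], int(face[0]), bary[0]
    return cp, face, bary


# -- rigid ICP ------------------------------------------------------------


def _principal_axes_init(ref: TriangleMesh, target: TriangleMesh, allow_scale: bool):
    """Centroid + PCA initialization; the 4 proper axis-sign combinations are
    scored by closest-point RMS and the best kept."""
    prox = SurfaceProximity(target)
    pr = ref.vertices - ref.vertices.mean(axis=0)
    qt = target.vertices - target.vertices.mean(axis=0)
    _, _, Vr = np.linalg.svd(pr, full_matrices=False)
    _, _, Vq = np.linalg.svd(qt, full_matrices=False)
    if np.linalg.det(Vr) < 0:
        Vr[2] = -Vr[2]
    if np.linalg.det(Vq) < 0:
        Vq[2] = -Vq[2]
    if allow_scale:
        s0 = np.sqrt((qt**2).sum(axis=1).mean() / (pr**2).sum(axis=1).mean())
    else:
        s0 = 1.0
    # candidate rotations: current pose first (preferred on ties — for time
    # series the meshes are already nearly aligned and near-symmetric shapes
    # make the PCA pose ambiguous), then the 4 proper PCA sign combinations
    candidates = [np.eye(3)]
    for signs in ([1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]):
        R = Vq.T @ np.diag(signs) @ Vr
        if np.linalg.det(R) > 0:
            candidates.append(R)
    best = None
    for R in candidates:
        t = target.vertices.mean(axis=0) - s0 * R @ ref.vertices.mean(axis=0)
        T = SimilarityTransform(rotation=R, scale=s0, translation=t)
        moved = T.apply(ref.vertices)
        cp, _, _ = prox.query(moved)
        rms = float(np.sqrt(((moved - cp) ** 2).sum(axis=1).mean()))
        if best is None or rms < best[0] * (1 - 1e-9):
            best = (rms, T)
    return best[1], prox


def rigid_align(
    ref: TriangleMesh,
    target: TriangleMesh,
    allow_scale: bool = True,
    max_iter: int = 60,
    tol: float = 1e-7,
) -> tuple[SimilarityTransform, TriangleMesh]:
    """ICP similarity registration of ``ref`` onto ``target``.

    Iterates closest-point correspondence + Procrustes until the RMS
    residual change drops below ``tol`` (relative to the target scale) or
    ``max_iter``; initialized by centroid/principal-axes alignment with the
    axis-sign ambiguity resolved by residual. Returns the transform and the
    transformed reference (UV preserved if present).
    """
    if ref.n_faces == 0 or target.n_faces == 0:
        raise ValueError("both meshes must be non-empty")
    T, prox = _principal_axes_init(ref, target, allow_scale)
    scale_ref = float(np.linalg.norm(target.vertices.std(axis=0)))
    history = []
    prev = np.inf
    converged = False
    for _ in range(max_iter):
        moved = T.apply(ref.vertices)
        cp, _, _ = prox.query(moved)
        rms = float(np.sqrt(((moved - cp) ** 2).sum(axis=1).mean()))
        history.append(rms)
        if abs(prev - rms) < tol * max(scale_ref, 1e-12):
            converged = True
            break
        prev = rms
        T_new = procrustes(ref.vertices, cp, allow_scale=allow_scale)
        T = T_new
    if not converged:
        warnings.warn("rigid_align did not converge within max_iter", stacklevel=2)
    T.residual_history = history
    T.converged = converged
    out = ref.copy()
    out.vertices = T.apply(ref.vertices)
    out.vertex_normals = None
    return T, out


# -- shrink-wrapping ------------------------------------------------------


def shrinkwrap(
    ref: TriangleMeshUV,
    target: TriangleMesh,
    iterations: int = 10,
    smooth_per_iter: int = 2,
    rigid_first: bool = True,
    allow_scale: bool = True,
) -> TriangleMeshUV:
    """Deform the reference onto the target by smoothed closest-point
    projection; the UV map is untouched.

    After (optional) rigid pre-alignment, each iteration projects every
    vertex to the closest target-surface point and applies Taubin smoothing
    to remove creases; a final pure projection guarantees the result lies on
    the target surface.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    work: TriangleMesh = ref
    if rigid_first:
        _, work = rigid_align(ref, target, allow_scale=allow_scale)
    prox = SurfaceProximity(target)
    v = work.vertices.copy()
    for _ in range(iterations):
        cp, _, _ = prox.query(v)
        v = cp
        if smooth_per_iter > 0:
            tmp = taubin_smooth(
                TriangleMesh(vertices=v, faces=ref.faces), smooth_per_iter
            )
            v = tmp.vertices
    cp, _, _ = prox.query(v)
    if isinstance(ref, TriangleMeshUV):
        return ref.with_vertices(cp)
    return TriangleMesh(vertices=cp, faces=ref.faces.copy())


# -- Möbius alignment -----------------------------------------------------


def _super_fibonacci_rotations(n: int) -> Rotation:
    """Deterministic quasi-uniform covering of SO(3) (super-Fibonacci
    spiral point set)."""
    phi = np.sqrt(2.0)
    psi = 1.533751168755204288118041
    i = np.arange(n)
    s = i + 0.5
    r = np.sqrt(s / n)
    R = np.sqrt(1.0 - s / n)
    alpha = 2 * np.pi * s / phi
    beta = 2 * np.pi * s / psi
    q = np.column_stack(
        [r * np.sin(alpha), r * np.cos(alpha), R * np.sin(beta), R * np.cos(beta)]
    )
    return Rotation.from_quat(q)


def conformal_descriptor(
    mesh: TriangleMesh, sphere_points: np.ndarray, smoothing_steps: int = 10
) -> np.ndarray:
    """Per-vertex log conformal area factor of the sphere map, diffused on
    the sphere by uniform neighbour averaging; zero-mean."""
    area3d = lumped_mass(mesh)
    sphere_mesh = TriangleMesh(vertices=sphere_points, faces=mesh.faces)
    area_s = lumped_mass(sphere_mesh)
    d = np.log(area3d / np.maximum(area_s, 1e-300))
    from .mesh import _uniform_adjacency

    adj = _uniform_adjacency(mesh)
    deg = np.asarray(adj.sum(axis=1)).ravel()
    deg[deg == 0] = 1.0
    for _ in range(smoothing_steps):
        d = 0.5 * d + 0.5 * (adj @ d) / deg
    return d - (area_s * d).sum() / area_s.sum()


def moebius_align(
    ref: TriangleMeshUV,
    target: TriangleMesh,
    rotation_grid: int = 128,
) -> TriangleMeshUV:
    """Align via conformal maps to the unit sphere.

    Both meshes are conformally mapped to the sphere; the residual Möbius
    freedom (after Möbius centering, a sphere rotation) is resolved by
    matching a rotation-grid-initialized, locally refined intrinsic
    descriptor (smoothed log conformal area factor). Each reference vertex
    is then carried through the composed map sphere→target and finally
    projected onto the target surface. The UV map is untouched.

    The descriptor choice is this package's own stand-in for the published
    Möbius-registration objective; it is intrinsic and rotation-invariant
    in 3D.
    """
    s_ref = conformal_sphere_map(ref)
    s_tgt = conformal_sphere_map(target)
    d_ref = conformal_descriptor(ref, s_ref)
    d_tgt = conformal_descriptor(target, s_tgt)
    w_ref = lumped_mass(TriangleMesh(vertices=s_ref, faces=ref.faces))
    sphere_tgt_mesh = TriangleMesh(vertices=s_tgt, faces=target.faces)
    prox_sphere = SurfaceProximity(sphere_tgt_mesh)

    def cost_of(R: np.ndarray) -> float:
        # barycentric descriptor interpolation keeps the cost piecewise
        # linear in the rotation, so local refinement can descend
        moved = s_ref @ R.T
        _, face, bary = prox_sphere.query(moved)
        d_interp = np.einsum("pk,pk->p", bary, d_tgt[target.faces[face]])
        return float((w_ref * (d_ref - d_interp) ** 2).sum() / w_ref.sum())

    rots = _super_fibonacci_rotations(max(int(rotation_grid), 1))
    costs = np.array([cost_of(r.as_matrix()) for r in rots])
    # the landscape is shallow and multimodal: refine several basins locally
    n_refine = min(8, len(costs))
    simplex = np.vstack([np.zeros(3), 0.25 * np.eye(3)])
    best_R, best_cost = None, np.inf
    for idx in np.argsort(costs)[:n_refine]:
        seed_rot = rots[int(idx)]

        def cost_vec(rv: np.ndarray) -> float:
            return cost_of((Rotation.from_rotvec(rv) * seed_rot).as_matrix())

        res = minimize(cost_vec, np.zeros(3), method="Nelder-Mead",
                       options={"xatol": 1e-5, "fatol": 1e-14, "maxiter": 400,
                                "initial_simplex": simplex})
        if res.fun < best_cost:
            best_cost = float(res.fun)
            best_R = (Rotation.from_rotvec(res.x) * seed_rot).as_matrix()
    R = best_R
    moved = s_ref @ R.T
    _, face, bary = prox_sphere.query(moved)
    tri = target.faces[face]
    deformed = np.einsum("pk,pkd->pd", bary, target.vertices[tri])
    # final closest-point projection onto the 3D target
    prox = SurfaceProximity(target)
    cp, _, _ = prox.query(deformed)
    if isinstance(ref, TriangleMeshUV):
        return ref.with_vertices(cp)
    return TriangleMesh(vertices=cp, faces=ref.faces.copy())


# -- sequences ------------------------------------------------------------


@dataclass
class Frame:
    mesh: TriangleMesh | TriangleMeshUV
    volume: VolumetricImage | None = None
    residual: float | None = None


@dataclass
class SurfaceSequence:
    """Ordered per-timepoint (volume, mesh) pairs with one UV reference."""

    frames: list[Frame]
    reference_index: int = 0

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("sequence needs at least one frame")
        if not 0 <= self.reference_index < len(self.frames):
            raise ValueError("reference index out of range")
        ref = self.frames[self.reference_index].mesh
        if not isinstance(ref, TriangleMeshUV):
            raise ValueError("reference frame must carry a UV map")


def _align_step(
    ref_mesh: TriangleMeshUV, target_mesh: TriangleMesh, method: str, **kwargs
) -> TriangleMeshUV:
    if method == "rigid":
        _, moved = rigid_align(ref_mesh, target_mesh, **kwargs)
        return moved  # copy keeps UV
    if method == "shrinkwrap":
        return shrinkwrap(ref_mesh, target_mesh, **kwargs)
    if method == "moebius":
        return moebius_align(ref_mesh, target_mesh, **kwargs)
    raise ValueError(f"unknown alignment method {method!r}")


def propagate_sequence(
    seq: SurfaceSequence, method: str = "shrinkwrap", **kwargs
) -> SurfaceSequence:
    """Transfer the reference frame's UV map to every frame.

    Frames are visited outward from the reference in both directions; each
    step aligns the previous frame's deformed, UV-carrying mesh onto the
    next frame's mesh. Per-frame RMS vertex-to-target residuals are stored
    on the frames.
    """
    n = len(seq.frames)
    ref_i = seq.reference_index
    out_frames: list[Frame | None] = [None] * n
    ref_frame = seq.frames[ref_i]
    out_frames[ref_i] = Frame(mesh=ref_frame.mesh.copy(), volume=ref_frame.volume,
                              residual=0.0)
    for direction in (+1, -1):
        prev = out_frames[ref_i].mesh
        i = ref_i + direction
        while 0 <= i < n:
            target = seq.frames[i].mesh
            try:
                moved = _align_step(prev, target, method, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"alignment failed at frame {i}: {exc}") from exc
            cp, _, _ = SurfaceProximity(target).query(moved.vertices)
            rms = float(np.sqrt(((moved.vertices - cp) ** 2).sum(axis=1).mean()))
            out_frames[i] = Frame(mesh=moved, volume=seq.frames[i].volume, residual=rms)
            prev = moved
            i += direction
    return SurfaceSequence(frames=out_frames, reference_index=ref_i)
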