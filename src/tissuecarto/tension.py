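"""Junction-network extraction and mechanical inference.

Assuming mechanical stress is concentrated along cell-cell interfaces,
relative interfacial tensions follow from the geometry of the interfaces
alone: at every tricellular vertex the (unit) interface tangents, weighted
by their tensions, must balance in the local tangent plane of the surface.
Tensions are relative — the gauge is fixed by normalizing their mean to 1.
The per-vertex stress tensor Σᵢ Tᵢ tᵢ⊗tᵢ (in the 2D tangent basis)
summarizes the local state; its deviatoric magnitude
|λ₁−λ₂|/(λ₁+λ₂) ∈ [0, 1] quantifies tension anisotropy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .analysis import uv_points_to_3d
from .mesh import TriangleMeshUV

DANGLING = -1  # interface endpoint outside the network (e.g. image border)


@dataclass
class Interface:
    """Cell-cell interface between two tricellular vertices.

    ``tangent_a``/``tangent_b`` are unit vectors at each endpoint, pointing
    *away* from that vertex along the interface, orthogonal to the local
    surface normal. Endpoint ``DANGLING`` marks an interface leaving the
    analyzed region.
    """

    vertex_a: int
    vertex_b: int
    cell_a: int
    cell_b: int
    tangent_a: np.ndarray | None = None
    tangent_b: np.ndarray | None = None

    def endpoints(self):
        out = []
        if self.vertex_a != DANGLING:
            out.append((self.vertex_a, self.tangent_a))
        if self.vertex_b != DANGLING:
            out.append((self.vertex_b, self.tangent_b))
        return out


@dataclass
class JunctionNetwork:
    """Tricellular vertices (3D, with surface normals) and their interfaces."""

    vertex_positions: np.ndarray  # (V, 3) μm
    vertex_normals: np.ndarray  # (V, 3) unit
    interfaces: list[Interface] = field(default_factory=list)
    vertex_uv: np.ndarray | None = None  # (V, 2), when extracted from a grid

    @property
    def n_vertices(self) -> int:
        return len(self.vertex_positions)

    @property
    def n_interfaces(self) -> int:
        return len(self.interfaces)

    def incidence(self) -> list[list[int]]:
        inc: list[list[int]] = [[] for _ in range(self.n_vertices)]
        for ei, itf in enumerate(self.interfaces):
            for v, _ in itf.endpoints():
                inc[v].append(ei)
        return inc

    def validate(self, tol: float = 1e-6) -> None:
        for itf in self.interfaces:
            for v, t in itf.endpoints():
                if t is None:
                    raise ValueError("endpoint tangent missing")
                if abs(float(t @ self.vertex_normals[v])) > tol:
                    raise ValueError("tangent not orthogonal to surface normal")
        for v, inc in enumerate(self.incidence()):
            if len(inc) < 3:
                raise ValueError(f"vertex {v} has degree {len(inc)} < 3")


@dataclass
class TensionSolution:
    tensions: np.ndarray  # (E,) relative, mean 1
    stress: np.ndarray  # (V, 2, 2) tangent-plane stress tensor
    anisotropy: np.ndarray  # (V,) deviatoric magnitude in [0, 1]
    clipped: np.ndarray  # (E,) bool, quality flag
    underdetermined: bool = False


def tangent_basis(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic orthonormal basis of the plane orthogonal to ``normal``."""
    n = np.asarray(normal, float)
    n = n / np.linalg.norm(n)
    helper = np.eye(3)[np.argmin(np.abs(n))]
    e1 = helper - (helper @ n) * n
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n, e1)
    return e1, e2


# -- extraction from a 2D segmentation -------------------------------------


def _lift_uv(mesh: TriangleMeshUV, uv: np.ndarray):
    pos, fidx, valid = uv_points_to_3d(mesh, uv)
    vn = mesh.ensure_vertex_normals()
    normals = np.full_like(pos, np.nan)
    ok = valid
    if ok.any():
        # barycentric normal at the lifted point
        from .analysis import uv_points_to_3d as _  # noqa: F401

        a, b, c = mesh.uv_face_corners()
        f = fidx[ok]
        p = uv[ok]
        det = (b[f, 0] - a[f, 0]) * (c[f, 1] - a[f, 1]) - (c[f, 0] - a[f, 0]) * (
            b[f, 1] - a[f, 1]
        )
        w1 = (
            (p[:, 0] - a[f, 0]) * (c[f, 1] - a[f, 1])
            - (c[f, 0] - a[f, 0]) * (p[:, 1] - a[f, 1])
        ) / det
        w2 = (
            (b[f, 0] - a[f, 0]) * (p[:, 1] - a[f, 1])
            - (p[:, 0] - a[f, 0]) * (b[f, 1] - a[f, 1])
        ) / det
        w = np.stack([1 - w1 - w2, w1, w2], axis=-1)
        tri = mesh.faces[f]
        nrm = np.einsum("pk,pkd->pd", w, vn[tri])
        nrm /= np.linalg.norm(nrm, axis=1, keepdims=True)
        normals[ok] = nrm
    return pos, normals, valid


def _cluster_points(points: np.ndarray, radius: float):
    """Greedy union of points closer than ``radius``; returns component labels."""
    n = len(points)
    parent = np.arange(n)

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    tree = cKDTree(points)
    for i, j in tree.query_pairs(radius):
        parent[find(i)] = find(j)
    labels = np.array([find(i) for i in range(n)])
    _, labels = np.unique(labels, return_inverse=True)
    return labels


def extract_junctions(
    labels: np.ndarray,
    mesh: TriangleMeshUV,
    k_tangent: int = 8,
    include_background: bool = False,
) -> JunctionNetwork:
    """Build the 3D junction network from a 2D cell segmentation.

    Tricellular vertices are pixel corners where ≥3 labels meet (adjacent
    corner candidates are merged), lifted to 3D through the UV map.
    Interface tangents at each endpoint are estimated from the mean of the
    first ``k_tangent`` interface boundary points next to the vertex, lifted
    to 3D and projected into the local tangent plane; the window trades the
    pixel-staircase quantization error of very short steps against chord
    bias on curved interfaces. Interfaces with the
    background (label 0) are ignored unless ``include_background``.
    Vertices lifting into the UV background are dropped with a warning.
    """
    labels = np.asarray(labels)
    rows, cols = labels.shape

    # pixel corners with >= 3 distinct labels among the 2x2 block
    blocks = np.stack(
        [labels[:-1, :-1], labels[:-1, 1:], labels[1:, :-1], labels[1:, 1:]]
    )
    srt = np.sort(blocks.reshape(4, -1), axis=0)
    distinct = 1 + (np.diff(srt, axis=0) != 0).sum(axis=0)
    distinct = distinct.reshape(rows - 1, cols - 1)
    ci, cj = np.nonzero(distinct >= 3)
    if len(ci) == 0:
        return JunctionNetwork(
            vertex_positions=np.zeros((0, 3)),
            vertex_normals=np.zeros((0, 3)),
            interfaces=[],
            vertex_uv=np.zeros((0, 2)),
        )
    corner_uv = np.column_stack([(cj + 1) / cols, 1.0 - (ci + 1) / rows])
    corner_labels = [set(int(x) for x in blocks[:, i, j]) for i, j in zip(ci, cj)]

    # merge adjacent corner candidates (within 1.5 px)
    px = 1.0 / max(rows, cols)
    comp = _cluster_points(corner_uv, 1.6 * px)
    n_junc = comp.max() + 1
    junc_uv = np.zeros((n_junc, 2))
    junc_labels: list[set] = [set() for _ in range(n_junc)]
    for k in range(n_junc):
        sel = comp == k
        junc_uv[k] = corner_uv[sel].mean(axis=0)
        for cl in np.nonzero(sel)[0]:
            junc_labels[k] |= corner_labels[cl]

    pos, normals, valid = _lift_uv(mesh, junc_uv)
    if not valid.all():
        warnings.warn(
            f"{int((~valid).sum())} junction(s) lift into UV background; dropped",
            stacklevel=2,
        )
    keep = np.nonzero(valid)[0]
    remap = {int(old): new for new, old in enumerate(keep)}
    junc_uv = junc_uv[keep]
    pos, normals = pos[keep], normals[keep]
    junc_labels = [junc_labels[i] for i in keep]

    # interface boundary points per label pair
    pair_points: dict[tuple[int, int], list[np.ndarray]] = {}

    def add_boundary(l1, l2, uu, vv):
        m = l1 != l2
        if not include_background:
            m &= (l1 != 0) & (l2 != 0)
        a = np.minimum(l1[m], l2[m])
        b = np.maximum(l1[m], l2[m])
        pts = np.column_stack([uu[m], vv[m]])
        for pa, pb, pt in zip(a, b, pts):
            pair_points.setdefault((int(pa), int(pb)), []).append(pt)

    jj, ii = np.meshgrid(np.arange(cols - 1), np.arange(rows))
    add_boundary(
        labels[:, :-1].ravel(),
        labels[:, 1:].ravel(),
        ((jj + 1) / cols).ravel(),
        (1.0 - (ii + 0.5) / rows).ravel(),
    )
    jj, ii = np.meshgrid(np.arange(cols), np.arange(rows - 1))
    add_boundary(
        labels[:-1, :].ravel(),
        labels[1:, :].ravel(),
        ((jj + 0.5) / cols).ravel(),
        (1.0 - (ii + 1) / rows).ravel(),
    )

    junc_tree = cKDTree(junc_uv) if len(junc_uv) else None
    interfaces: list[Interface] = []
    for (la, lb), pts in sorted(pair_points.items()):
        pts = np.asarray(pts)
        cand = [
            v
            for v in range(len(junc_uv))
            if {la, lb} <= junc_labels[v]
        ]
        if not cand:
            continue
        # endpoints: the two candidate junctions nearest to the point cloud ends
        dists = {v: np.linalg.norm(pts - junc_uv[v], axis=1).min() for v in cand}
        close = [v for v in cand if dists[v] < 3.0 * px]
        if len(close) >= 2:
            # two most distant mutually
            best = None
            for x in close:
                for y in close:
                    if x < y:
                        d = np.linalg.norm(junc_uv[x] - junc_uv[y])
                        if best is None or d > best[0]:
                            best = (d, x, y)
            va, vb = best[1], best[2]
        elif len(close) == 1:
            va, vb = close[0], DANGLING
        else:
            continue

        def tangent_at(v: int) -> np.ndarray | None:
            d = np.linalg.norm(pts - junc_uv[v], axis=1)
            order = np.argsort(d)
            take = order[: min(k_tangent, len(order))]
            step = pts[take].mean(axis=0) - junc_uv[v]
            norm = np.linalg.norm(step)
            if norm < 1e-12:
                return None
            step = step / norm
            # lift direction through the chart at the junction
            eps = 0.25 * px
            p0, _, ok0 = uv_points_to_3d(mesh, junc_uv[v][None])
            p1, _, ok1 = uv_points_to_3d(mesh, (junc_uv[v] + eps * step)[None])
            if not (ok0[0] and ok1[0]):
                return None
            t = p1[0] - p0[0]
            n = normals[v]
            t = t - (t @ n) * n
            nt = np.linalg.norm(t)
            return t / nt if nt > 0 else None

        ta = tangent_at(va) if va != DANGLING else None
        tb = tangent_at(vb) if vb != DANGLING else None
        if va != DANGLING and ta is None:
            continue
        if vb != DANGLING and tb is None:
            vb = DANGLING
        interfaces.append(
            Interface(
                vertex_a=va, vertex_b=vb, cell_a=la, cell_b=lb,
                tangent_a=ta, tangent_b=tb,
            )
        )

    net = JunctionNetwork(
        vertex_positions=pos,
        vertex_normals=normals,
        interfaces=interfaces,
        vertex_uv=junc_uv,
    )
    return _prune_low_degree(net)


def _prune_low_degree(net: JunctionNetwork, min_degree: int = 3) -> JunctionNetwork:
    """Drop vertices with degree < min_degree (their interfaces dangle)."""
    inc = net.incidence()
    keep = np.array([len(x) >= min_degree for x in inc])
    if keep.all():
        return net
    remap = -np.ones(net.n_vertices, int)
    remap[keep] = np.arange(keep.sum())
    interfaces = []
    for itf in net.interfaces:
        va = remap[itf.vertex_a] if itf.vertex_a != DANGLING else DANGLING
        vb = remap[itf.vertex_b] if itf.vertex_b != DANGLING else DANGLING
        if va == DANGLING and vb == DANGLING:
            continue
        interfaces.append(
            Interface(
                vertex_a=int(va), vertex_b=int(vb),
                cell_a=itf.cell_a, cell_b=itf.cell_b,
                tangent_a=itf.tangent_a if va != DANGLING else None,
                tangent_b=itf.tangent_b if vb != DANGLING else None,
            )
        )
    return JunctionNetwork(
        vertex_positions=net.vertex_positions[keep],
        vertex_normals=net.vertex_normals[keep],
        interfaces=interfaces,
        vertex_uv=None if net.vertex_uv is None else net.vertex_uv[keep],
    )


# -- inference --------------------------------------------------------------


def _components(net: JunctionNetwork) -> list[tuple[list[int], list[int]]]:
    """Connected components as (vertex ids, interface ids)."""
    parent = list(range(net.n_vertices))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for itf in net.interfaces:
        if itf.vertex_a != DANGLING and itf.vertex_b != DANGLING:
            parent[find(itf.vertex_a)] = find(itf.vertex_b)
    comp_of = [find(v) for v in range(net.n_vertices)]
    roots = sorted(set(comp_of))
    out = []
    for r in roots:
        vs = [v for v in range(net.n_vertices) if comp_of[v] == r]
        vset = set(vs)
        es = [
            ei
            for ei, itf in enumerate(net.interfaces)
            if (itf.vertex_a in vset) or (itf.vertex_b in vset)
        ]
        out.append((vs, es))
    return out


def infer_tensions(net: JunctionNetwork, floor: float = 1e-3) -> TensionSolution:
    """Solve the tangent-plane force balance for relative tensions.

    At every tricellular vertex, Σᵢ Tᵢ tᵢ ≈ 0 projected onto the vertex's
    2D tangent basis (the normal component of the imbalance is discarded —
    stresses are assumed in-plane). The constrained least squares fixes the
    gauge with mean(T) = 1 per connected component; underdetermined
    components (fewer balance equations than free tensions) are flagged and
    set to T = 1. Negative tensions are clipped to a small positive floor
    with a quality flag.
    """
    if net.n_vertices < 1:
        raise ValueError("network needs at least one tricellular vertex")
    E = net.n_interfaces
    tensions = np.ones(E)
    clipped = np.zeros(E, bool)
    underdet = False
    inc = net.incidence()
    for vs, es in _components(net):
        if not es:
            continue
        col = {e: k for k, e in enumerate(es)}
        nE = len(es)
        rows = []
        for v in vs:
            e1, e2 = tangent_basis(net.vertex_normals[v])
            r1 = np.zeros(nE)
            r2 = np.zeros(nE)
            for ei in inc[v]:
                itf = net.interfaces[ei]
                t = itf.tangent_a if itf.vertex_a == v else itf.tangent_b
                r1[col[ei]] += float(t @ e1)
                r2[col[ei]] += float(t @ e2)
            rows += [r1, r2]
        A = np.vstack(rows)
        if A.shape[0] < nE - 1:
            underdet = True
            for e in es:
                tensions[e] = 1.0
            continue
        # minimize ||A T||² subject to mean(T) = 1 (KKT system)
        c = np.ones(nE)
        K = np.zeros((nE + 1, nE + 1))
        K[:nE, :nE] = 2 * A.T @ A
        K[:nE, nE] = c
        K[nE, :nE] = c
        rhs = np.zeros(nE + 1)
        rhs[nE] = float(nE)
        sol, *_ = np.linalg.lstsq(K, rhs, rcond=None)
        T = sol[:nE]
        neg = T <= 0
        if neg.any():
            T = np.maximum(T, floor)
            T *= nE / T.sum()
            for k, e in enumerate(es):
                clipped[e] = neg[k]
        for k, e in enumerate(es):
            tensions[e] = T[k]
    stress, anis = vertex_stress(net, tensions)
    return TensionSolution(
        tensions=tensions,
        stress=stress,
        anisotropy=anis,
        clipped=clipped,
        underdetermined=underdet,
    )


def vertex_stress(
    net: JunctionNetwork, tensions: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-vertex tangent-plane stress tensor σ = Σᵢ Tᵢ tᵢ⊗tᵢ and its
    deviatoric anisotropy |λ₁−λ₂|/(λ₁+λ₂) ∈ [0, 1]."""
    V = net.n_vertices
    stress = np.zeros((V, 2, 2))
    anis = np.zeros(V)
    inc = net.incidence()
    for v in range(V):
        e1, e2 = tangent_basis(net.vertex_normals[v])
        sigma = np.zeros((2, 2))
        for ei in inc[v]:
            itf = net.interfaces[ei]
            t = itf.tangent_a if itf.vertex_a == v else itf.tangent_b
            t2 = np.array([float(t @ e1), float(t @ e2)])
            sigma += tensions[ei] * np.outer(t2, t2)
        stress[v] = sigma
        lam = np.linalg.eigvalsh(sigma)
        tr = lam.sum()
        anis[v] = abs(lam[1] - lam[0]) / tr if tr > 0 else 0.0
    return stress, anis


def network_to_frames(net: JunctionNetwork, solution: TensionSolution | None = None):
    """Tabular export: (interfaces DataFrame, vertices DataFrame)."""
    import pandas as pd

    itf_rows = []
    for ei, itf in enumerate(net.interfaces):
        row = {
            "interface": ei,
            "vertex_a": itf.vertex_a,
            "vertex_b": itf.vertex_b,
            "cell_a": itf.cell_a,
            "cell_b": itf.cell_b,
        }
        if solution is not None:
            row["tension"] = solution.tensions[ei]
            row["clipped"] = bool(solution.clipped[ei])
        itf_rows.append(row)
    v_rows = []
    for v in range(net.n_vertices):
        row = {
            "vertex": v,
            "x": net.vertex_positions[v, 0],
            "y": net.vertex_positions[v, 1],
            "z": net.vertex_positions[v, 2],
        }
        if net.vertex_uv is not None:
            row["u"], row["v_uv"] = net.vertex_uv[v]
        if solution is not None:
            row["stress_11"] = solution.stress[v, 0, 0]
            row["stress_12"] = solution.stress[v, 0, 1]
            row["stress_22"] = solution.stress[v, 1, 1]
            row["anisotropy"] = solution.anisotropy[v]
        v_rows.append(row)
    return pd.DataFrame(itf_rows), pd.DataFrame(v_rows)
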