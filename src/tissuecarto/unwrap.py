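"""Cartographic unwrapping: UV parameterization of surface meshes.

Provides the classic axis/spherical/cylindrical chart projections, seam
cutting (opening a closed surface into disk topology), discrete-harmonic
flattening of disk patches, and a conformal map of genus-0 surfaces to the
unit sphere (the reference shape used for Möbius alignment).

Orientation convention: triangles facing outward in 3D have positive signed
area in the UV square. A 1% margin inside the unit square is reserved by the
flattening/axis charts so pullback grids keep a background border.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .mesh import (
    TriangleMesh,
    TriangleMeshUV,
    attach_uv,
    cotangent_laplacian,
    face_adjacency_components,
    lumped_mass,
)

UV_MARGIN = 0.01


@dataclass
class SeamPath:
    """Ordered, edge-connected path (or loop) of mesh vertex indices."""

    vertices: list[int]

    def edge_pairs(self) -> list[tuple[int, int]]:
        v = list(self.vertices)
        return [tuple(sorted((v[i], v[i + 1]))) for i in range(len(v) - 1)]


def _fit_to_square(
    uv: np.ndarray, margin: float = UV_MARGIN, preserve_aspect: bool = True
) -> np.ndarray:
    """Affinely rescale 2D points into ``[margin, 1-margin]²``."""
    lo = uv.min(axis=0)
    hi = uv.max(axis=0)
    span = hi - lo
    span[span == 0] = 1.0
    if preserve_aspect:
        scale = (1 - 2 * margin) / span.max()
        out = (uv - lo) * scale
        # centre the short dimension
        out = out + (1 - 2 * margin - span * scale) / 2
    else:
        out = (uv - lo) * (1 - 2 * margin) / span
    return out + margin


def _orthonormal_frame(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Right-handed frame ``(e1, e2, axis)`` with ``e1 × e2 = axis``."""
    axis = np.asarray(axis, float)
    n = np.linalg.norm(axis)
    if n < 1e-12:
        raise ValueError("degenerate axis (norm 0)")
    axis = axis / n
    helper = np.eye(3)[np.argmin(np.abs(axis))]
    e1 = np.cross(helper, axis)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    return e1, e2, axis


def uv_axis_projection(mesh: TriangleMesh, axis: np.ndarray) -> TriangleMeshUV:
    """Project along ``axis``: UV are the two in-plane coordinates.

    Suitable for surfaces representable as a height field along the axis;
    folded-over regions are permitted but produce overlapping UV (warned).
    """
    e1, e2, ax = _orthonormal_frame(axis)
    uv = np.column_stack([mesh.vertices @ e1, mesh.vertices @ e2])
    f = mesh.faces
    a, b, c = uv[f[:, 0]], uv[f[:, 1]], uv[f[:, 2]]
    signed = (b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1]) - (c[:, 0] - a[:, 0]) * (
        b[:, 1] - a[:, 1]
    )
    if signed.sum() < 0:
        uv[:, 0] = -uv[:, 0]  # mirror so outward-facing faces are positive
    uv = _fit_to_square(uv)
    out = attach_uv(mesh, uv, mesh.faces.copy())
    if mesh.vertex_normals is not None:
        if np.any(mesh.vertex_normals @ ax < 0):
            warnings.warn(
                "surface folds over along the projection axis; UV overlaps",
                stacklevel=2,
            )
    return out


def _angular_uv(
    mesh: TriangleMesh,
    u: np.ndarray,
    v: np.ndarray,
    pole_mask: np.ndarray,
) -> TriangleMeshUV:
    """Assemble a UV mesh from per-vertex (u, v) where u is periodic in [0,1).

    Faces straddling the u=0/1 wrap are cut: the minority-side corners are
    duplicated in UV and shifted across the seam, with out-of-range values
    clamped to the square (distortion confined to seam-adjacent faces).
    Vertices flagged in ``pole_mask`` have undefined u and receive a
    per-face duplicate with the mean u of the face's other corners.
    """
    uv_vertices = list(np.column_stack([u, v]))
    uv_faces = np.array(mesh.faces, copy=True)
    dup_cache: dict[tuple[int, int], int] = {}

    def dup(vertex: int, uu: float, vv: float, side: int) -> int:
        key = (vertex, side)
        if key not in dup_cache:
            uv_vertices.append(np.array([np.clip(uu, 0.0, 1.0), vv]))
            dup_cache[key] = len(uv_vertices) - 1
        return dup_cache[key]

    for fi, face in enumerate(mesh.faces):
        poles = pole_mask[face]
        us = u[face]
        regular = ~poles
        if regular.sum() == 0:
            continue
        ur = us[regular]
        straddle = ur.max() - ur.min() > 0.5
        if straddle:
            low = ur[ur <= 0.5]
            high = ur[ur > 0.5]
            # pick the shift side that clamps the least out-of-range excursion
            cost_up = low.max() if len(low) else 0.0  # low corners -> u+1
            cost_down = 1.0 - high.min() if len(high) else 0.0  # high -> u-1
            if cost_up <= cost_down:
                for ci in range(3):
                    if regular[ci] and us[ci] <= 0.5:
                        uv_faces[fi, ci] = dup(face[ci], us[ci] + 1.0, v[face[ci]], +1)
            else:
                for ci in range(3):
                    if regular[ci] and us[ci] > 0.5:
                        uv_faces[fi, ci] = dup(face[ci], us[ci] - 1.0, v[face[ci]], -1)
        if poles.any():
            cur_u = np.array(
                [uv_vertices[uv_faces[fi, ci]][0] for ci in range(3) if regular[ci]]
            )
            for ci in range(3):
                if poles[ci]:
                    uv_vertices.append(
                        np.array([float(cur_u.mean()), v[face[ci]]])
                    )
                    uv_faces[fi, ci] = len(uv_vertices) - 1
    return attach_uv(mesh, np.vstack(uv_vertices), uv_faces, strict=False)


def uv_spherical(
    mesh: TriangleMesh,
    center: np.ndarray = (0.0, 0.0, 0.0),
    pole_axis: np.ndarray = (0.0, 0.0, 1.0),
    meridian_axis: np.ndarray = (1.0, 0.0, 0.0),
) -> TriangleMeshUV:
    """Lat-long chart: u = longitude / 2π from ``meridian_axis`` about
    ``pole_axis``; v = 1 − colatitude/π (v=1 at the +pole).

    The vertex on the meridian at the equator maps to (0, 0.5). Faces
    straddling the u seam are cut by UV-vertex duplication.
    """
    center = np.asarray(center, float)
    pole = np.asarray(pole_axis, float)
    pole = pole / np.linalg.norm(pole)
    mer = np.asarray(meridian_axis, float)
    mer = mer / np.linalg.norm(mer)
    if abs(pole @ mer) > 1e-6:
        raise ValueError("pole_axis and meridian_axis must be orthogonal")
    third = np.cross(pole, mer)
    p = mesh.vertices - center
    r = np.linalg.norm(p, axis=1)
    if np.any(r < 1e-12):
        raise ValueError("vertex coincident with projection center")
    x = p @ mer
    y = p @ third
    z = np.clip(p @ pole / r, -1.0, 1.0)
    theta = np.arccos(z)  # colatitude
    pole_mask = np.hypot(x, y) < 1e-9 * r.max()
    phi = np.arctan2(y, x)
    u = np.mod(phi / (2 * np.pi), 1.0)
    v = 1.0 - theta / np.pi
    return _angular_uv(mesh, u, v, pole_mask)


def uv_cylindrical(
    mesh: TriangleMesh,
    axis_point: np.ndarray,
    axis_dir: np.ndarray,
    meridian_axis: np.ndarray,
) -> TriangleMeshUV:
    """Cylindrical chart: u = angle/2π about the axis, v = normalized
    position along the axis. The tube unrolls isometrically up to the fixed
    u/v scales."""
    axis_point = np.asarray(axis_point, float)
    k = np.asarray(axis_dir, float)
    k = k / np.linalg.norm(k)
    mer = np.asarray(meridian_axis, float)
    mer = mer - (mer @ k) * k
    if np.linalg.norm(mer) < 1e-9:
        raise ValueError("meridian_axis parallel to axis_dir")
    mer /= np.linalg.norm(mer)
    third = np.cross(k, mer)
    p = mesh.vertices - axis_point
    h = p @ k
    radial = p - h[:, None] * k
    rad = np.linalg.norm(radial, axis=1)
    if np.any(rad < 1e-12):
        raise ValueError("vertex lies on the projection axis")
    phi = np.arctan2(radial @ third, radial @ mer)
    u = np.mod(phi / (2 * np.pi), 1.0)
    span = h.max() - h.min()
    span = span if span > 0 else 1.0
    v = (h - h.min()) / span
    pole_mask = np.zeros(mesh.n_vertices, bool)
    return _angular_uv(mesh, u, v, pole_mask)


# -- seam cutting ---------------------------------------------------------


def cut_mesh_along_seams(
    mesh: TriangleMesh, seams: list[SeamPath | list[int]]
) -> TriangleMesh:
    """Cut the mesh open along seam paths, duplicating vertices per side.

    The 3D geometry is unchanged; faces on either side of a cut edge
    reference separate copies of the seam vertices. The result must be a
    union of disk-topology patches (checked via the Euler characteristic),
    otherwise an error names the characteristic found.
    """
    mesh_edges = {tuple(e) for e in map(tuple, mesh.edges())}
    cut_edges: set[tuple[int, int]] = set()
    for seam in seams:
        path = seam.vertices if isinstance(seam, SeamPath) else list(seam)
        if len(path) < 2:
            raise ValueError("seam path needs at least 2 vertices")
        for a, b in zip(path[:-1], path[1:]):
            edge = tuple(sorted((int(a), int(b))))
            if edge not in mesh_edges:
                raise ValueError(f"seam not edge-connected: {edge} is not a mesh edge")
            cut_edges.add(edge)

    vertices = [v for v in mesh.vertices]
    faces = np.array(mesh.faces, copy=True)

    # faces incident to each cut vertex
    cut_vertices = sorted({v for e in cut_edges for v in e})
    incident: dict[int, list[int]] = {v: [] for v in cut_vertices}
    for fi, face in enumerate(mesh.faces):
        for v in face:
            if int(v) in incident:
                incident[int(v)].append(fi)

    for v in cut_vertices:
        fids = incident[v]
        # union faces sharing a non-cut edge through v
        parent = {f: f for f in fids}

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        edge_to_faces: dict[tuple[int, int], list[int]] = {}
        for f in fids:
            face = mesh.faces[f]
            for i in range(3):
                a, b = int(face[i]), int(face[(i + 1) % 3])
                if v in (a, b):
                    edge_to_faces.setdefault(tuple(sorted((a, b))), []).append(f)
        for edge, flist in edge_to_faces.items():
            if edge in cut_edges or len(flist) < 2:
                continue
            r = find(flist[0])
            for f in flist[1:]:
                parent[find(f)] = r
        groups: dict[int, list[int]] = {}
        for f in fids:
            groups.setdefault(find(f), []).append(f)
        group_list = sorted(groups.values(), key=lambda g: min(g))
        for g in group_list[1:]:
            vertices.append(mesh.vertices[v].copy())
            new_idx = len(vertices) - 1
            for f in g:
                faces[f][faces[f] == v] = new_idx

    out = TriangleMesh(vertices=np.vstack(vertices), faces=faces)
    # every connected component must now be a disk
    labels = face_adjacency_components(out.faces)
    for comp in range(labels.max() + 1):
        patch = out.faces[labels == comp]
        vs = np.unique(patch)
        e = np.unique(
            np.sort(
                np.concatenate([patch[:, [0, 1]], patch[:, [1, 2]], patch[:, [2, 0]]]),
                axis=1,
            ),
            axis=0,
        )
        chi = len(vs) - len(e) + len(patch)
        if chi != 1:
            raise ValueError(
                f"cut result is not a disk (Euler characteristic {chi})"
            )
    return out


# -- harmonic disk flattening --------------------------------------------


def _boundary_loop(mesh: TriangleMesh) -> list[int]:
    directed = mesh.boundary_edges()
    if len(directed) == 0:
        raise ValueError("mesh has no boundary (not a disk)")
    succ = {int(a): int(b) for a, b in directed}
    if len(succ) != len(directed):
        raise ValueError("non-manifold boundary")
    start = min(succ)
    loop = [start]
    cur = succ[start]
    while cur != start:
        loop.append(cur)
        cur = succ[cur]
        if len(loop) > len(directed):
            raise ValueError("boundary is not a single loop")
    if len(loop) != len(directed):
        raise ValueError("boundary is not a single loop")
    return loop


def uv_harmonic_disk(cut_mesh: TriangleMesh) -> TriangleMeshUV:
    """Harmonic flattening of a disk patch to a circle.

    The boundary is mapped to a circle by arc length (starting at the lowest
    boundary vertex index); interior vertices solve the discrete Laplace
    equation with cotangent weights clamped non-negative, which guarantees a
    bijection onto the convex (circular) boundary. Output is rescaled into
    ``[0.01, 0.99]²``.
    """
    if len(np.unique(face_adjacency_components(cut_mesh.faces))) != 1:
        raise ValueError("input must be a single connected patch")
    if cut_mesh.euler_characteristic() != 1:
        raise ValueError(
            f"input is not a disk (Euler characteristic {cut_mesh.euler_characteristic()})"
        )
    loop = _boundary_loop(cut_mesh)
    pts = cut_mesh.vertices[loop]
    seg = np.linalg.norm(np.roll(pts, -1, axis=0) - pts, axis=1)
    total = seg.sum()
    arc = np.concatenate([[0.0], np.cumsum(seg[:-1])])
    theta = 2 * np.pi * arc / total
    boundary_uv = np.column_stack([np.cos(theta), np.sin(theta)])

    n = cut_mesh.n_vertices
    L = cotangent_laplacian(cut_mesh, clamp=True)
    is_boundary = np.zeros(n, bool)
    is_boundary[loop] = True
    interior = np.where(~is_boundary)[0]
    uv = np.zeros((n, 2))
    uv[loop] = boundary_uv
    if len(interior):
        L_ii = L[interior][:, interior].tocsc()
        L_ib = L[interior][:, loop]
        rhs = -L_ib @ boundary_uv
        try:
            solve = spla.factorized(L_ii)
        except RuntimeError as exc:  # singular factorization
            raise ValueError(f"singular harmonic solve: {exc}") from exc
        sol = np.column_stack([solve(rhs[:, 0]), solve(rhs[:, 1])])
        if not np.all(np.isfinite(sol)):
            raise ValueError("singular harmonic solve (non-finite solution)")
        uv[interior] = sol
    f = cut_mesh.faces
    a, b, c = uv[f[:, 0]], uv[f[:, 1]], uv[f[:, 2]]
    signed = (b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1]) - (c[:, 0] - a[:, 0]) * (
        b[:, 1] - a[:, 1]
    )
    if signed.sum() < 0:
        uv[:, 0] = -uv[:, 0]  # enforce outward-positive orientation
    uv = _fit_to_square(uv)
    return attach_uv(cut_mesh, uv, cut_mesh.faces.copy())


# -- conformal sphere map -------------------------------------------------


def _moebius_center(points: np.ndarray, areas_fn, tol: float = 1e-8, max_iter: int = 200):
    """Möbius-center unit-sphere points so the area-weighted centroid is ~0.

    Applies damped sphere inversions ``T_a(p) = (1-|a|²)(p+a)/|p+a|² + a``
    (which map the unit sphere to itself) until the centroid vanishes.
    """
    pts = points.copy()
    for _ in range(max_iter):
        w = areas_fn(pts)
        com = (w[:, None] * pts).sum(axis=0) / w.sum()
        if np.linalg.norm(com) < tol:
            break
        a = -0.5 * com
        denom = np.linalg.norm(pts + a, axis=1, keepdims=True) ** 2
        pts = (1 - a @ a) * (pts + a) / denom + a
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    return pts


def conformal_sphere_map(
    mesh: TriangleMesh,
    dt: float = 0.05,
    max_iter: int = 300,
    sphericity_tol: float = 1e-4,
) -> np.ndarray:
    """Conformal map of a closed genus-0 mesh onto the unit sphere.

    Uses conformalized mean-curvature flow: the vertex positions diffuse
    under the *initial* cotangent Laplacian (implicit Euler steps) with
    recentring and rescaling each step, which converges to a conformal
    spherical embedding; the result is Möbius-centred so the area-weighted
    centroid of the image is the sphere centre, then projected exactly onto
    the unit sphere. Returns per-vertex unit positions.
    """
    if not mesh.is_watertight() or mesh.euler_characteristic() != 2:
        raise ValueError(
            "conformal sphere map requires a closed genus-0 mesh "
            f"(Euler characteristic {mesh.euler_characteristic()})"
        )
    V = mesh.vertices.copy()
    V = V - V.mean(axis=0)
    V /= np.sqrt((V**2).sum(axis=1).mean())
    L = cotangent_laplacian(mesh)
    faces = mesh.faces
    prev_sphericity = np.inf
    for _ in range(max_iter):
        M = lumped_mass(TriangleMesh(vertices=V, faces=faces))
        A = (sp.diags(M) - dt * L).tocsc()
        V = spla.spsolve(A, M[:, None] * V)
        M2 = lumped_mass(TriangleMesh(vertices=V, faces=faces))
        V = V - (M2[:, None] * V).sum(axis=0) / M2.sum()
        r = np.linalg.norm(V, axis=1)
        V /= r.mean()
        sphericity = float(np.abs(np.linalg.norm(V, axis=1) - 1).max())
        if sphericity < sphericity_tol or abs(prev_sphericity - sphericity) < 1e-8:
            break
        prev_sphericity = sphericity
    V /= np.linalg.norm(V, axis=1, keepdims=True)

    def areas_fn(pts: np.ndarray) -> np.ndarray:
        return lumped_mass(TriangleMesh(vertices=pts, faces=faces))

    V = _moebius_center(V, areas_fn)
    V /= np.linalg.norm(V, axis=1, keepdims=True)
    return V
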