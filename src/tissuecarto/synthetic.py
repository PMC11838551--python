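"""Ground-truth fixtures emulating tissue-cartography inputs.

Generates shell volumes (a fluorescent layer wrapped around a curved
surface, like labelled nuclei or membranes around an embryo), analytic
meshes, dynamic sequences with exact material-point correspondence, and
synthetic cell segmentations with known interfacial tensions. Everything is
deterministic under a fixed seed; all randomness flows through one seeded
generator per call.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import trimesh as _trimesh
from scipy.spatial import Delaunay, cKDTree

from .mesh import TriangleMesh, TriangleMeshUV
from .volume import BinaryMask, VolumetricImage

# -- implicit shapes -------------------------------------------------------


class Shape:
    """Implicit surface: ``implicit`` < 0 inside, > 0 outside."""

    def implicit(self, p: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def gradient(self, p: np.ndarray, h: float = 1e-4) -> np.ndarray:
        g = np.empty_like(p, dtype=float)
        for d in range(3):
            dp = np.zeros(3)
            dp[d] = h
            g[..., d] = (self.implicit(p + dp) - self.implicit(p - dp)) / (2 * h)
        return g

    def surface_project(self, p: np.ndarray, steps: int = 4) -> np.ndarray:
        """Newton projection of points onto the zero set."""
        q = np.array(p, dtype=float)
        for _ in range(steps):
            f = self.implicit(q)
            g = self.gradient(q)
            g2 = np.maximum((g**2).sum(axis=-1), 1e-300)
            q = q - (f / g2)[..., None] * g
        return q

    def signed_distance(self, p: np.ndarray) -> np.ndarray:
        q = self.surface_project(p)
        d = np.linalg.norm(np.asarray(p, float) - q, axis=-1)
        return np.sign(self.implicit(p)) * d

    def bounding_radius(self) -> float:  # pragma: no cover
        raise NotImplementedError


@dataclass(frozen=True)
class Sphere(Shape):
    radius: float

    def implicit(self, p):
        return np.linalg.norm(np.asarray(p, float), axis=-1) - self.radius

    def signed_distance(self, p):
        return self.implicit(p)

    def surface_project(self, p, steps: int = 0):
        p = np.asarray(p, float)
        r = np.linalg.norm(p, axis=-1, keepdims=True)
        return self.radius * p / np.maximum(r, 1e-300)

    def bounding_radius(self):
        return self.radius

    @property
    def axes(self):
        return np.full(3, self.radius)


@dataclass(frozen=True)
class Ellipsoid(Shape):
    a: float
    b: float
    c: float

    @property
    def axes(self):
        return np.array([self.a, self.b, self.c])

    def implicit(self, p):
        q = np.asarray(p, float) / self.axes
        return np.linalg.norm(q, axis=-1) - 1.0

    def bounding_radius(self):
        return float(self.axes.max())


@dataclass(frozen=True)
class BumpySphere(Shape):
    """Sphere with angular radius modulation — a shape with no rotational
    symmetry, useful for registration ground truth."""

    radius: float
    amplitude: float = 0.1
    frequency: int = 3

    def _local_radius(self, d: np.ndarray) -> np.ndarray:
        theta = np.arccos(np.clip(d[..., 2], -1, 1))
        phi = np.arctan2(d[..., 1], d[..., 0])
        f = self.frequency
        # mixed frequencies so the shape has no rotational/mirror symmetry
        mod = np.cos(f * theta) * np.cos(f * phi) + 0.5 * np.sin(
            (f - 1) * theta
        ) * np.sin((f + 1) * phi + 1.0)
        return self.radius * (1.0 + self.amplitude * mod)

    def implicit(self, p):
        p = np.asarray(p, float)
        r = np.linalg.norm(p, axis=-1)
        d = p / np.maximum(r, 1e-300)[..., None]
        return r - self._local_radius(d)

    def bounding_radius(self):
        return self.radius * (1 + abs(self.amplitude))


@dataclass(frozen=True)
class Tube(Shape):
    """Capsule (cylinder with hemispherical caps) along the x axis."""

    radius: float
    length: float  # cylindrical segment length

    def implicit(self, p):
        p = np.asarray(p, float)
        x = np.clip(p[..., 0], -self.length / 2, self.length / 2)
        axis_pt = np.stack([x, np.zeros_like(x), np.zeros_like(x)], axis=-1)
        return np.linalg.norm(p - axis_pt, axis=-1) - self.radius

    def signed_distance(self, p):
        return self.implicit(p)  # exact for a capsule

    def bounding_radius(self):
        return self.length / 2 + self.radius


@dataclass
class GroundTruth:
    """What the generator knows exactly: the implicit surface, its normals,
    the texture on it, the frame deformation maps and the placement of the
    shape inside the voxel grid."""

    shape: Shape
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    texture: Callable[[np.ndarray], np.ndarray] | None = None
    seed: int | None = None
    frame_axes: list[np.ndarray] | None = None  # ellipsoid semi-axes per frame

    def normal(self, p: np.ndarray) -> np.ndarray:
        g = self.shape.gradient(np.asarray(p, float) - self.center)
        return g / np.linalg.norm(g, axis=-1, keepdims=True)

    def implicit(self, p: np.ndarray) -> np.ndarray:
        return self.shape.implicit(np.asarray(p, float) - self.center)

    def map_between(self, frame_from: int, frame_to: int, points: np.ndarray) -> np.ndarray:
        """Exact material-point correspondence for ellipsoid-family
        sequences: points share the same unit-sphere preimage."""
        if self.frame_axes is None:
            raise ValueError("not a sequence ground truth")
        a0 = self.frame_axes[frame_from]
        a1 = self.frame_axes[frame_to]
        q = (np.asarray(points, float) - self.center) / a0
        q /= np.linalg.norm(q, axis=-1, keepdims=True)
        return q * a1 + self.center


# -- analytic meshes -------------------------------------------------------


def make_mesh(shape: Shape, resolution: int = 3) -> TriangleMesh:
    """Analytic, watertight mesh of a shape with exact normals.

    ``resolution`` is the icosphere subdivision level for round shapes
    (10·4ⁿ+2 vertices) and the section count parameter for tubes.
    """
    if isinstance(shape, Sphere):
        ico = _trimesh.creation.icosphere(subdivisions=resolution, radius=1.0)
        v = np.asarray(ico.vertices) * shape.radius
        mesh = TriangleMesh(vertices=v, faces=np.asarray(ico.faces))
        mesh.vertex_normals = v / np.linalg.norm(v, axis=1, keepdims=True)
        return mesh
    if isinstance(shape, Ellipsoid):
        ico = _trimesh.creation.icosphere(subdivisions=resolution, radius=1.0)
        d = np.asarray(ico.vertices)
        v = d * shape.axes
        n = d / shape.axes  # gradient of the quadratic form, unnormalized
        n /= np.linalg.norm(n, axis=1, keepdims=True)
        mesh = TriangleMesh(vertices=v, faces=np.asarray(ico.faces))
        mesh.vertex_normals = n
        return mesh
    if isinstance(shape, BumpySphere):
        ico = _trimesh.creation.icosphere(subdivisions=resolution, radius=1.0)
        d = np.asarray(ico.vertices)
        v = d * shape._local_radius(d)[:, None]
        mesh = TriangleMesh(vertices=v, faces=np.asarray(ico.faces))
        g = shape.gradient(v)
        mesh.vertex_normals = g / np.linalg.norm(g, axis=1, keepdims=True)
        return mesh
    if isinstance(shape, Tube):
        count = 4 * (2**resolution)
        cap = _trimesh.creation.capsule(
            height=shape.length, radius=shape.radius, count=(count, count)
        )
        v = np.asarray(cap.vertices)
        # trimesh builds the capsule along z, centred; re-orient along x
        v = np.column_stack([v[:, 2] - shape.length / 2, v[:, 1], v[:, 0]])
        faces = np.asarray(cap.faces)[:, ::-1]  # axis swap flips parity
        mesh = TriangleMesh(vertices=v, faces=faces)
        if mesh.signed_volume() < 0:
            mesh.faces = mesh.faces[:, ::-1]
        g = shape.gradient(mesh.vertices)
        mesh.vertex_normals = g / np.linalg.norm(g, axis=1, keepdims=True)
        return mesh
    raise TypeError(f"no analytic mesh for {type(shape).__name__}")


# -- shell volumes ----------------------------------------------------------


def _make_texture(
    texture: str | tuple, shape: Shape, rng: np.random.Generator
) -> Callable[[np.ndarray], np.ndarray]:
    """Texture value as a function of points on (or near) the surface."""
    if texture == "uniform":
        return lambda p: np.ones(np.asarray(p).shape[:-1])
    if isinstance(texture, tuple) and texture[0] == "checkerboard":
        period = float(texture[1])  # angular period in radians

        def checker(p):
            p = np.asarray(p, float)
            r = np.linalg.norm(p, axis=-1)
            d = p / np.maximum(r, 1e-300)[..., None]
            theta = np.arccos(np.clip(d[..., 2], -1, 1))
            phi = np.mod(np.arctan2(d[..., 1], d[..., 0]), 2 * np.pi)
            par = np.floor(theta / period) + np.floor(phi / period)
            return np.where(np.mod(par, 2) == 0, 1.0, 0.25)

        return checker
    if isinstance(texture, tuple) and texture[0] == "cells":
        n = int(texture[1])
        dirs = rng.normal(size=(n, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        values = 0.3 + 0.7 * rng.random(n)
        tree = cKDTree(dirs)

        def cells(p):
            p = np.asarray(p, float)
            r = np.linalg.norm(p, axis=-1, keepdims=True)
            d = p / np.maximum(r, 1e-300)
            _, idx = tree.query(d.reshape(-1, 3))
            return values[idx].reshape(p.shape[:-1])

        return cells
    raise ValueError(f"unknown texture {texture!r}")


def make_shell_volume(
    shape: Shape,
    spacing: float | tuple = 1.0,
    shell_thickness: float = 2.0,
    texture: str | tuple = "uniform",
    noise_sigma: float = 0.0,
    seed: int = 0,
    margin_voxels: int = 3,
    grid_shape: tuple[int, int, int] | None = None,
) -> tuple[VolumetricImage, BinaryMask, GroundTruth]:
    """Synthetic fluorescent shell around an implicit surface.

    Channel-0 intensity is ``texture(surface point) × exp(−d²/2σ²)`` with
    ``d`` the signed distance to the surface and ``σ = shell_thickness/2``,
    plus additive Gaussian noise; the mask is the solid interior
    (``implicit ≤ 0``). Fully deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)
    spacing = np.broadcast_to(np.asarray(spacing, float).ravel(), (3,)).copy()  # (dz, dy, dx)
    R = shape.bounding_radius()
    if grid_shape is None:
        half = R + (margin_voxels + 0.5) * spacing
        # grid sizes so voxel centres span [-half, half] around the centre
        nz = int(np.ceil(2 * half[0] / spacing[0])) + 1
        ny = int(np.ceil(2 * half[1] / spacing[1])) + 1
        nx = int(np.ceil(2 * half[2] / spacing[2])) + 1
        grid_shape = (nz, ny, nx)
    else:
        nz, ny, nx = grid_shape
        if (
            R + margin_voxels * spacing[0] > (nz - 1) / 2 * spacing[0]
            or R + margin_voxels * spacing[1] > (ny - 1) / 2 * spacing[1]
            or R + margin_voxels * spacing[2] > (nx - 1) / 2 * spacing[2]
        ):
            raise ValueError("shape exceeds the requested volume")
        nz, ny, nx = grid_shape
    center = np.array(
        [(nx - 1) / 2 * spacing[2], (ny - 1) / 2 * spacing[1], (nz - 1) / 2 * spacing[0]]
    )  # (x, y, z) μm
    zz, yy, xx = np.meshgrid(
        np.arange(nz) * spacing[0],
        np.arange(ny) * spacing[1],
        np.arange(nx) * spacing[2],
        indexing="ij",
    )
    pts = np.stack([xx, yy, zz], axis=-1) - center  # (Z, Y, X, 3) shape frame
    d = shape.signed_distance(pts)
    sigma = shell_thickness / 2.0
    profile = np.exp(-(d**2) / (2 * sigma**2))
    tex_fn = _make_texture(texture, shape, rng)
    near = np.abs(d) < 4 * sigma
    tex = np.ones_like(d)
    if near.any():
        surf_pts = shape.surface_project(pts[near])
        tex[near] = tex_fn(surf_pts)
    intensity = tex * profile
    if noise_sigma > 0:
        intensity = intensity + rng.normal(0.0, noise_sigma, size=intensity.shape)
    image = VolumetricImage(data=intensity[None], spacing=spacing)
    mask = BinaryMask(data=shape.implicit(pts) <= 0, spacing=spacing)
    gt = GroundTruth(shape=shape, center=center, texture=tex_fn, seed=seed)
    return image, mask, gt


# -- sequences --------------------------------------------------------------


def _as_axes(shape: Shape) -> np.ndarray:
    if isinstance(shape, (Sphere, Ellipsoid)):
        return np.asarray(shape.axes, float)
    raise TypeError("sequences support sphere/ellipsoid shapes")


def make_sequence(
    shape_start: Shape,
    shape_end: Shape,
    n_frames: int,
    seed: int = 0,
    mesh_resolution: int = 3,
    include_volumes: bool = False,
    **shell_kwargs,
) -> list[tuple[VolumetricImage | None, TriangleMesh, GroundTruth]]:
    """Linear interpolation between two ellipsoid-family shapes.

    Every frame's ground truth carries the exact material-point
    correspondence (shared unit-sphere preimage) between all frames, so
    alignment algorithms can be scored against known homologous points.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    a0 = _as_axes(shape_start)
    a1 = _as_axes(shape_end)
    ts = np.linspace(0.0, 1.0, n_frames) if n_frames > 1 else np.array([0.0])
    axes_list = [(1 - t) * a0 + t * a1 for t in ts]
    frames = []
    for k, ax in enumerate(axes_list):
        if np.allclose(ax, ax[0]):
            shape: Shape = Sphere(float(ax[0]))
        else:
            shape = Ellipsoid(*map(float, ax))
        mesh = make_mesh(shape, resolution=mesh_resolution)
        volume = None
        center = np.zeros(3)
        if include_volumes:
            volume, _, gtv = make_shell_volume(shape, seed=seed + k, **shell_kwargs)
            center = gtv.center
            mesh = TriangleMesh(
                vertices=mesh.vertices + center,
                faces=mesh.faces,
                vertex_normals=mesh.vertex_normals,
            )
        gt = GroundTruth(
            shape=shape, center=center, seed=seed, frame_axes=axes_list
        )
        frames.append((volume, mesh, gt))
    return frames


# -- cell segmentations with known tensions ---------------------------------


def _hex_seeds(n_cells: int) -> np.ndarray:
    """Hexagonal lattice of ~n_cells seeds tiling the unit square.

    Row spacing is exactly √3/2 of the column spacing with alternate rows
    offset by half a column — a perfect triangular lattice, so interior
    Voronoi cells are regular hexagons (120° junctions, equal dual edge
    lengths). Rows are centred on the square rather than stretched to tile
    it, preserving exact lattice geometry."""
    nx = max(int(round(np.sqrt(n_cells * np.sqrt(3) / 2))), 2)
    dx = 1.0 / nx
    dy = dx * np.sqrt(3) / 2
    ny = max(int(round(1.0 / dy)), 2)
    xs = (np.arange(nx) + 0.5) * dx
    ys = 0.5 + (np.arange(ny) - (ny - 1) / 2) * dy
    pts = []
    for j, y in enumerate(ys):
        off = 0.25 * dx if j % 2 else -0.25 * dx
        for x in xs:
            pts.append([x + off, y])
    return np.asarray(pts)


def _circumcenters(points: np.ndarray, tris: np.ndarray) -> np.ndarray:
    """Circumcenters of 2D triangles (the dual/Voronoi vertices)."""
    a, b, c = points[tris[:, 0]], points[tris[:, 1]], points[tris[:, 2]]
    ab = b - a
    ac = c - a
    d = 2 * (ab[:, 0] * ac[:, 1] - ab[:, 1] * ac[:, 0])
    d = np.where(np.abs(d) < 1e-300, np.inf, d)
    ab2 = (ab**2).sum(axis=1)
    ac2 = (ac**2).sum(axis=1)
    ux = (ac[:, 1] * ab2 - ab[:, 1] * ac2) / d
    uy = (ab[:, 0] * ac2 - ac[:, 0] * ab2) / d
    return a + np.column_stack([ux, uy])


def make_cell_labels(
    mesh: TriangleMeshUV,
    n_cells: int,
    grid_shape: tuple[int, int],
    seed: int = 0,
    tension_model: str | tuple = "uniform",
) -> tuple[np.ndarray, "LabelGroundTruth"]:
    """Synthetic cell segmentation on the UV grid with known tensions.

    Cells are the Voronoi tessellation of a hexagonal lattice of seeds;
    tricellular junctions are the circumcenters of the dual Delaunay
    triangles. Tensions are constructed by the reciprocal-diagram
    (Maxwell–Cremona) principle: the tension of each cell–cell interface is
    the length of its dual Delaunay edge, which the perpendicularity of the
    Voronoi diagram makes *exactly* balanced at every junction — the three
    weighted tangents are the 90°-rotated, closed edge cycle of the dual
    triangle. ``tension_model="uniform"`` uses the perfect lattice (regular
    honeycomb, all tensions 1, 120° junctions); ``("heterogeneous", sigma)``
    jitters the seeds so interface tensions spread by roughly ``sigma``
    (relative) while remaining exactly recoverable from the geometry.
    Returns the label image and the ground-truth junction network.
    """
    if n_cells < 3:
        raise ValueError("n_cells must be >= 3")
    rows, cols = grid_shape
    rng = np.random.default_rng(seed)
    seeds = _hex_seeds(n_cells)
    n_orig = len(seeds)
    spacing_x = 1.0 / int(round(np.sqrt(n_orig * np.sqrt(3) / 2)))
    if isinstance(tension_model, tuple) and tension_model[0] == "heterogeneous":
        sigma = float(tension_model[1])
        seeds = seeds + rng.normal(0.0, sigma * spacing_x / np.sqrt(2), seeds.shape)
        seeds = np.clip(seeds, 0.02, 0.98)
    elif tension_model != "uniform":
        raise ValueError(f"unknown tension model {tension_model!r}")

    # mirror seeds across the four square edges so border cells are bounded
    mirrored = [seeds]
    for dim, edge in ((0, 0.0), (0, 1.0), (1, 0.0), (1, 1.0)):
        m = seeds.copy()
        m[:, dim] = 2 * edge - m[:, dim]
        mirrored.append(m)
    allpts = np.vstack(mirrored)
    tri = Delaunay(allpts)
    simplices = tri.simplices.copy()
    # orient all dual triangles counter-clockwise
    a, b, c = (allpts[simplices[:, k]] for k in range(3))
    cw = np.cross(b - a, c - a) < 0
    simplices[cw] = simplices[cw][:, [0, 2, 1]]
    centers = _circumcenters(allpts, simplices)

    # label image: nearest original seed (Voronoi, clipped to the square)
    u = (np.arange(cols) + 0.5) / cols
    v = 1.0 - (np.arange(rows) + 0.5) / rows
    U, Vv = np.meshgrid(u, v)
    pix = np.column_stack([U.ravel(), Vv.ravel()])
    _, nearest = cKDTree(seeds).query(pix)
    labels = (nearest + 1).astype(np.int32).reshape(rows, cols)

    # junctions: circumcenters of all-original triangles, inside the square
    margin = 1e-6
    is_orig = simplices < n_orig
    inside = (
        np.all(is_orig, axis=1)
        & (centers[:, 0] > margin)
        & (centers[:, 0] < 1 - margin)
        & (centers[:, 1] > margin)
        & (centers[:, 1] < 1 - margin)
    )
    kept_tris = np.nonzero(inside)[0]
    jmap = {int(t): k for k, t in enumerate(kept_tris)}
    junc_uv = centers[kept_tris]

    # dual edges: map each Delaunay edge to its (up to 2) triangles
    edge_tris: dict[tuple[int, int], list[int]] = {}
    for ti, s in enumerate(simplices):
        for k in range(3):
            e = tuple(sorted((int(s[k]), int(s[(k + 1) % 3]))))
            edge_tris.setdefault(e, []).append(ti)

    from .tension import DANGLING, Interface, JunctionNetwork

    # lift junctions through the chart
    pos3, _, valid = uv_points_to_3d_cached(mesh, junc_uv)
    if not valid.all():
        raise ValueError("lattice junction lifts into UV background")
    vn = mesh.ensure_vertex_normals()
    normals3 = np.zeros_like(pos3)
    for k in range(len(junc_uv)):
        _, fidx_, _ = uv_points_to_3d_cached(mesh, junc_uv[k][None])
        f = mesh.faces[fidx_[0]]
        nrm = vn[f].mean(axis=0)
        normals3[k] = nrm / np.linalg.norm(nrm)

    def lift_dir(uv_pt, direction):
        eps = 1e-4
        p0, _, _ = uv_points_to_3d_cached(mesh, uv_pt[None])
        p1, _, ok = uv_points_to_3d_cached(mesh, (uv_pt + eps * direction)[None])
        if not ok[0]:
            p1, _, _ = uv_points_to_3d_cached(mesh, (uv_pt - eps * direction)[None])
            t = p0[0] - p1[0]
        else:
            t = p1[0] - p0[0]
        return t / np.linalg.norm(t)

    net_interfaces: list[Interface] = []
    gt_tensions: list[float] = []
    for (i, j), tris_e in sorted(edge_tris.items()):
        if i >= n_orig or j >= n_orig:
            continue
        ends = [jmap.get(int(t), DANGLING) for t in tris_e]
        if len(ends) == 1:
            ends.append(DANGLING)
        if ends[0] == DANGLING and ends[1] == DANGLING:
            continue
        if ends[0] == DANGLING:
            ends = ends[::-1]
            tris_e = tris_e[::-1]
        ia, ib = ends
        ca, cb = i + 1, j + 1
        # dual (Voronoi) edge direction: between the two circumcenters,
        # which lie on the perpendicular bisector of seed edge (i, j)
        c0 = centers[tris_e[0]]
        c1 = centers[tris_e[1]] if len(tris_e) > 1 else None
        if c1 is not None and np.linalg.norm(c1 - c0) > 1e-9:
            d01 = (c1 - c0) / np.linalg.norm(c1 - c0)
        else:
            # degenerate/missing partner: perpendicular to the seed edge,
            # oriented away from the triangle's third vertex
            e_dir = allpts[j] - allpts[i]
            d01 = np.array([-e_dir[1], e_dir[0]])
            d01 /= np.linalg.norm(d01)
            s = simplices[tris_e[0]]
            third = [p for p in s if p not in (i, j)][0]
            mid = 0.5 * (allpts[i] + allpts[j])
            if d01 @ (mid - allpts[third]) < 0:
                d01 = -d01

        ta = tb = None
        if ia != DANGLING:
            t3 = lift_dir(junc_uv[ia], d01)
            n = normals3[ia]
            t3 = t3 - (t3 @ n) * n
            ta = t3 / np.linalg.norm(t3)
        if ib != DANGLING:
            t3 = lift_dir(junc_uv[ib], -d01)
            n = normals3[ib]
            t3 = t3 - (t3 @ n) * n
            tb = t3 / np.linalg.norm(t3)
        net_interfaces.append(
            Interface(vertex_a=int(ia), vertex_b=int(ib), cell_a=ca, cell_b=cb,
                      tangent_a=ta, tangent_b=tb)
        )
        gt_tensions.append(float(np.linalg.norm(allpts[i] - allpts[j])))

    gt_tensions = np.asarray(gt_tensions)
    gt_tensions /= gt_tensions.mean()
    network = JunctionNetwork(
        vertex_positions=pos3,
        vertex_normals=normals3,
        interfaces=net_interfaces,
        vertex_uv=junc_uv,
    )
    gt = LabelGroundTruth(
        network=network,
        tensions=gt_tensions,
        n_cells=n_orig,
        seed=seed,
        junction_uv=junc_uv,
    )
    return labels, gt


def uv_points_to_3d_cached(mesh, pts):
    from .analysis import uv_points_to_3d

    return uv_points_to_3d(mesh, pts)


@dataclass
class LabelGroundTruth:
    """Generator-side truth for a synthetic cell segmentation."""

    network: "object"
    tensions: np.ndarray
    n_cells: int
    seed: int
    junction_uv: np.ndarray
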