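"""Pullback projection: sample volumetric intensities onto the UV grid.

Each pixel of the output grid is located inside a UV triangle, its 3D
position and outward normal interpolated barycentrically from the mesh, and
the volume sampled trilinearly at ``position + offset · normal`` for each
requested layer ("onion peeling"). The grid, not the mesh, sets the output
resolution. Pixel-centre convention: pixel ``(i, j)`` on an R×C grid maps to
``u = (j+0.5)/C``, ``v = 1 − (i+0.5)/R`` (image row 0 is the top of the UV
square). Background pixels carry fill value 0 plus a validity mask.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage

from .mesh import TriangleMesh, TriangleMeshUV
from .volume import VolumetricImage

FILL_VALUE = 0.0


@dataclass
class RasterMap:
    """Per-pixel UV-triangle lookup: face index (−1 = background) and
    barycentric weights."""

    face_index: np.ndarray  # (R, C) int
    barycentric: np.ndarray  # (R, C, 3) float

    @property
    def valid(self) -> np.ndarray:
        return self.face_index >= 0


@dataclass
class PullbackProjection:
    """Multilayer, multichannel cartographic projection on the UV grid."""

    intensity: np.ndarray  # (layer, channel, R, C)
    positions: np.ndarray  # (3, R, C) μm, (x, y, z)
    normals: np.ndarray  # (3, R, C) unit outward
    valid: np.ndarray  # (R, C) bool
    offsets: list[float]  # signed μm per layer (+ = outward)
    grid_shape: tuple[int, int]
    in_volume: np.ndarray | None = None  # (layer, R, C): sample inside volume


def pixel_centers_uv(grid_shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    rows, cols = grid_shape
    u = (np.arange(cols) + 0.5) / cols
    v = 1.0 - (np.arange(rows) + 0.5) / rows
    return u, v


def rasterize_uv(mesh: TriangleMeshUV, grid_shape: tuple[int, int]) -> RasterMap:
    """Locate each pixel centre inside a UV triangle.

    Faces are scanned in ascending index order and only unassigned pixels are
    claimed, so overlapping UV triangles resolve to the lowest face index
    (with a warning).
    """
    rows, cols = grid_shape
    if rows < 1 or cols < 1:
        raise ValueError("grid must have at least one row and column")
    if len(mesh.uv_faces) != len(mesh.faces):
        raise ValueError("uv_faces must correspond one-to-one with faces")
    if len(mesh.uv_vertices) and (
        mesh.uv_vertices.min() < -1e-9 or mesh.uv_vertices.max() > 1 + 1e-9
    ):
        raise ValueError("UV coordinates must lie in the unit square")
    # zero-area UV faces (e.g. chart slivers at spherical poles) cover no
    # pixel centres; they are skipped rather than rejected here
    face_index = -np.ones((rows, cols), dtype=np.int64)
    bary = np.zeros((rows, cols, 3))
    a, b, c = mesh.uv_face_corners()
    overlap = 0
    tol = 1e-9
    for f in range(len(mesh.uv_faces)):
        ua, ub, uc = a[f], b[f], c[f]
        umin = min(ua[0], ub[0], uc[0])
        umax = max(ua[0], ub[0], uc[0])
        vmin = min(ua[1], ub[1], uc[1])
        vmax = max(ua[1], ub[1], uc[1])
        j0 = max(int(np.floor(umin * cols - 0.5)), 0)
        j1 = min(int(np.ceil(umax * cols - 0.5)), cols - 1)
        i0 = max(int(np.floor((1 - vmax) * rows - 0.5)), 0)
        i1 = min(int(np.ceil((1 - vmin) * rows - 0.5)), rows - 1)
        if j1 < j0 or i1 < i0:
            continue
        jj = np.arange(j0, j1 + 1)
        ii = np.arange(i0, i1 + 1)
        uu = (jj + 0.5) / cols
        vv = 1.0 - (ii + 0.5) / rows
        U, Vv = np.meshgrid(uu, vv)
        det = (ub[0] - ua[0]) * (uc[1] - ua[1]) - (uc[0] - ua[0]) * (ub[1] - ua[1])
        if abs(det) < 1e-15:
            continue
        w1 = ((U - ua[0]) * (uc[1] - ua[1]) - (uc[0] - ua[0]) * (Vv - ua[1])) / det
        w2 = ((ub[0] - ua[0]) * (Vv - ua[1]) - (U - ua[0]) * (ub[1] - ua[1])) / det
        w0 = 1.0 - w1 - w2
        inside = (w0 >= -tol) & (w1 >= -tol) & (w2 >= -tol)
        if not inside.any():
            continue
        sub_fi = face_index[i0 : i1 + 1, j0 : j1 + 1]
        strict = (w0 > tol) & (w1 > tol) & (w2 > tol)
        overlap += int(np.count_nonzero(strict & (sub_fi >= 0)))
        claim = inside & (sub_fi < 0)
        sub_fi[claim] = f
        sub_b = bary[i0 : i1 + 1, j0 : j1 + 1]
        sub_b[claim] = np.stack([w0[claim], w1[claim], w2[claim]], axis=-1)
    if overlap:
        warnings.warn(
            f"{overlap} pixel centres covered by overlapping UV triangles; "
            "kept lowest face index",
            stacklevel=2,
        )
    return RasterMap(face_index=face_index, barycentric=bary)


def _interpolate_mesh_maps(
    mesh: TriangleMeshUV, raster: RasterMap
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel 3D position and (renormalized) outward normal maps."""
    valid = raster.valid
    fidx = raster.face_index[valid]
    w = raster.barycentric[valid]
    corners = mesh.faces[fidx]  # (P, 3)
    pos = np.einsum("pk,pkd->pd", w, mesh.vertices[corners])
    vn = mesh.ensure_vertex_normals()
    nrm = np.einsum("pk,pkd->pd", w, vn[corners])
    lens = np.linalg.norm(nrm, axis=1, keepdims=True)
    lens[lens == 0] = 1.0
    nrm = nrm / lens
    rows, cols = raster.face_index.shape
    positions = np.zeros((3, rows, cols))
    normals = np.zeros((3, rows, cols))
    for d in range(3):
        positions[d][valid] = pos[:, d]
        normals[d][valid] = nrm[:, d]
    return positions, normals


def sample_volume_at(
    image: VolumetricImage, points: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Trilinear sample of every channel at physical (x, y, z) points.

    Returns ``(values (C, P), inside (P,))`` with fill value 0 outside the
    volume's voxel-centre extent.
    """
    idx = image.world_to_index(points)  # (P, 3) fractional (z, y, x)
    shape = np.array(image.spatial_shape, float)
    inside = np.all((idx >= 0) & (idx <= shape - 1), axis=-1)
    if np.any(~np.isfinite(image.data)):
        warnings.warn("volume contains NaN; they propagate into samples", stacklevel=2)
    coords = idx.T  # (3, P)
    values = np.stack(
        [
            ndimage.map_coordinates(
                image.data[ch].astype(np.float64),
                coords,
                order=1,
                mode="constant",
                cval=FILL_VALUE,
            )
            for ch in range(image.n_channels)
        ]
    )
    return values, inside


def pullback(
    image: VolumetricImage,
    mesh: TriangleMeshUV,
    grid_shape: tuple[int, int],
    offsets: list[float] | None = None,
) -> PullbackProjection:
    """Multilayer pullback of the volume onto the UV grid.

    ``offsets`` are signed μm distances along the outward surface normal
    (positive = out of the tissue; a layer "20 μm inwards" is offset −20).
    """
    if offsets is None:
        offsets = [0.0]
    raster = rasterize_uv(mesh, grid_shape)
    positions, normals = _interpolate_mesh_maps(mesh, raster)
    valid = raster.valid
    rows, cols = grid_shape
    n_layers = len(offsets)
    intensity = np.full(
        (n_layers, image.n_channels, rows, cols), FILL_VALUE, dtype=np.float64
    )
    in_volume = np.zeros((n_layers, rows, cols), bool)
    pos_pts = np.stack([positions[d][valid] for d in range(3)], axis=-1)
    nrm_pts = np.stack([normals[d][valid] for d in range(3)], axis=-1)
    for li, d in enumerate(offsets):
        samples = pos_pts + d * nrm_pts
        values, inside = sample_volume_at(image, samples)
        for ch in range(image.n_channels):
            intensity[li, ch][valid] = values[ch]
        in_volume[li][valid] = inside
    return PullbackProjection(
        intensity=intensity,
        positions=positions,
        normals=normals,
        valid=valid,
        offsets=list(offsets),
        grid_shape=(rows, cols),
        in_volume=in_volume,
    )


def vertex_shade(
    image: VolumetricImage, mesh: TriangleMesh, offset: float = 0.0
) -> np.ndarray:
    """Sample the volume at mesh vertices (+ optional normal offset).

    Returns per-channel, per-vertex intensities ``(C, N)``. No UV map is
    consulted; out-of-volume vertices get fill value 0.
    """
    pts = mesh.vertices
    if offset != 0.0:
        pts = pts + offset * mesh.ensure_vertex_normals()
    values, _ = sample_volume_at(image, pts)
    return values


# -- output ---------------------------------------------------------------


def write_pullback(stem: str | Path, proj: PullbackProjection) -> dict[str, Path]:
    """Write projection TIFFs: intensity pages layer-major/channel-minor,
    plus ``_xyz``, ``_normals`` and ``_valid`` companions."""
    stem = Path(stem)
    n_layers, n_channels, rows, cols = proj.intensity.shape
    paths = {}
    main = stem.with_suffix(".tif")
    tifffile.imwrite(
        main,
        proj.intensity.reshape(n_layers * n_channels, rows, cols).astype(np.float32),
        metadata={
            "axes": "QYX",
            "page_order": "layer-major, channel-minor",
            "offsets_um": list(map(float, proj.offsets)),
            "n_layers": n_layers,
            "n_channels": n_channels,
        },
    )
    paths["intensity"] = main
    xyz = stem.parent / (stem.name + "_xyz.tif")
    tifffile.imwrite(xyz, proj.positions.astype(np.float32), metadata={"axes": "SYX"})
    paths["positions"] = xyz
    nrm = stem.parent / (stem.name + "_normals.tif")
    tifffile.imwrite(nrm, proj.normals.astype(np.float32), metadata={"axes": "SYX"})
    paths["normals"] = nrm
    val = stem.parent / (stem.name + "_valid.tif")
    tifffile.imwrite(val, proj.valid.astype(np.uint8))
    paths["valid"] = val
    return paths
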