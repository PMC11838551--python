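"""Surface extraction: segmentation of the solid object and meshing of its
boundary (the surface of interest).

The meshing path is marching cubes on a (optionally Gaussian-pre-smoothed)
binary mask, with largest-connected-component filtering at both the voxel
and the mesh stage, vertex coordinates scaled into μm, and outward
orientation enforced via the signed volume.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage
from skimage.measure import marching_cubes
from skimage.segmentation import morphological_chan_vese

from .mesh import (
    TriangleMesh,
    largest_component,
    remove_degenerate_faces,
    taubin_smooth,
)
from .volume import BinaryMask, VolumetricImage


def _ball_footprint(radius: int) -> np.ndarray:
    r = int(radius)
    z, y, x = np.mgrid[-r : r + 1, -r : r + 1, -r : r + 1]
    return (z * z + y * y + x * x) <= r * r


def binarize_volume(
    image: VolumetricImage,
    channel: int = 0,
    threshold: float = 0.5,
    closing_radius: int = 0,
    smooth_sigma: float = 0.0,
) -> BinaryMask:
    """Threshold one channel into a solid binary mask.

    The channel is optionally Gaussian-smoothed (``smooth_sigma`` in voxels,
    0 disables), thresholded at ``>= threshold``, morphologically closed with
    a ball of ``closing_radius`` voxels, and reduced to its largest connected
    component. Stands in for interactive pixel-classification segmentation.
    """
    data = image.channel(channel).astype(np.float64)
    lo, hi = float(data.min()), float(data.max())
    if not lo <= threshold <= hi:
        raise ValueError(
            f"threshold {threshold} outside intensity range [{lo}, {hi}]"
        )
    if smooth_sigma > 0:
        data = ndimage.gaussian_filter(data, smooth_sigma)
    mask = data >= threshold
    if closing_radius > 0:
        mask = ndimage.binary_closing(mask, structure=_ball_footprint(closing_radius))
    labels, n = ndimage.label(mask)
    if n == 0:
        raise ValueError("empty segmentation")
    if n > 1:
        counts = np.bincount(labels.ravel())[1:]
        mask = labels == (1 + counts.argmax())
    return BinaryMask(data=mask, spacing=image.spacing)


def refine_mask_levelset(
    mask: BinaryMask,
    image: VolumetricImage,
    channel: int = 0,
    iterations: int = 20,
    smoothing: int = 1,
) -> BinaryMask:
    """Region-based level-set (morphological Chan–Vese) refinement of a mask.

    Evolves the mask as the initial level set against the chosen channel for
    a fixed number of iterations; ``iterations=0`` returns the input
    unchanged.
    """
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    data = image.channel(channel)
    if data.shape != mask.spatial_shape:
        raise ValueError(
            f"mask shape {mask.spatial_shape} != image shape {data.shape}"
        )
    if iterations == 0:
        return BinaryMask(data=mask.data.copy(), spacing=mask.spacing)
    refined = morphological_chan_vese(
        data.astype(np.float64),
        num_iter=int(iterations),
        init_level_set=mask.data,
        smoothing=smoothing,
    )
    return BinaryMask(data=refined.astype(bool), spacing=mask.spacing)


def mask_to_mesh(
    mask: BinaryMask,
    level: float = 0.5,
    smooth_sigma: float = 1.0,
    keep_largest: bool = True,
) -> TriangleMesh:
    """Marching-cubes isosurface of a binary mask, in μm, outward-oriented.

    By default the binary mask is Gaussian-smoothed (σ=1 voxel) before
    contouring, which suppresses the staircase artifacts (and systematic
    area overestimate) of raw binary marching cubes; pass ``smooth_sigma=0``
    for the raw isosurface. Output is the largest connected component with
    degenerate faces removed, and outward vertex normals.
    """
    if not mask.data.any():
        raise ValueError("no isosurface: mask is all false")
    if mask.data.all():
        raise ValueError("no isosurface: mask is all true")
    vol = mask.data.astype(np.float64)
    if smooth_sigma > 0:
        vol = ndimage.gaussian_filter(vol, smooth_sigma)
    verts_zyx, faces, _, _ = marching_cubes(vol, level=level, spacing=tuple(mask.spacing))
    vertices = verts_zyx[:, ::-1]  # (z,y,x)·spacing -> (x,y,z) μm
    mesh = TriangleMesh(vertices=vertices, faces=faces)
    mesh = remove_degenerate_faces(mesh)
    if keep_largest:
        mesh = largest_component(mesh)
    # axis reversal flips parity; enforce outward orientation explicitly
    if mesh.signed_volume() < 0:
        mesh.faces = mesh.faces[:, ::-1]
    mesh.vertex_normals = mesh.compute_vertex_normals()
    return mesh


def smooth_mesh(
    mesh: TriangleMesh, iterations: int, lam: float = 0.5, mu: float = -0.53
) -> TriangleMesh:
    """Taubin smoothing of the surface mesh (``mu=0`` for pure Laplacian)."""
    if iterations > 0 and not (lam > 0):
        warnings.warn("Taubin smoothing expects lam > 0", stacklevel=2)
    out = taubin_smooth(mesh, iterations, lam=lam, mu=mu)
    if iterations > 0:
        out.vertex_normals = out.compute_vertex_normals()
    return out
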