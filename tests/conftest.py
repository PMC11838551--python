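"""Shared fixtures: analytic meshes, flat charts, synthetic volumes."""

from __future__ import annotations

import numpy as np
import pytest

from tissuecarto.mesh import TriangleMesh, attach_uv
from tissuecarto.synthetic import Ellipsoid, Sphere, make_mesh, make_shell_volume
from tissuecarto.volume import VolumetricImage


@pytest.fixture(scope="session")
def unit_icosphere() -> TriangleMesh:
    return make_mesh(Sphere(1.0), 3)


@pytest.fixture(scope="session")
def fine_icosphere() -> TriangleMesh:
    return make_mesh(Sphere(1.0), 4)


@pytest.fixture(scope="session")
def ellipsoid_211() -> TriangleMesh:
    return make_mesh(Ellipsoid(2.0, 1.0, 1.0), 4)


def grid_mesh(n: int = 11, scale: float = 100.0, z: float = 0.0) -> TriangleMesh:
    """Regular triangulated square in the z-plane, side ``scale`` μm."""
    g = np.linspace(0.0, 1.0, n)
    X, Y = np.meshgrid(g, g)
    V = np.column_stack([X.ravel() * scale, Y.ravel() * scale, np.full(X.size, z)])
    F = []
    for i in range(n - 1):
        for j in range(n - 1):
            a = i * n + j
            b, c, d = a + 1, a + n, a + n + 1
            F.append([a, b, d])
            F.append([a, d, c])
    return TriangleMesh(vertices=V, faces=np.asarray(F))


def flat_uv_mesh(n: int = 11, scale: float = 100.0, z: float = 0.0):
    """Flat mesh whose UV map is the identity chart on the unit square."""
    mesh = grid_mesh(n=n, scale=scale, z=z)
    uv = mesh.vertices[:, :2] / scale
    return attach_uv(mesh, uv, mesh.faces.copy())


@pytest.fixture(scope="session")
def flat_chart():
    return flat_uv_mesh()


def cylinder_mesh(radius=1.0, height=2.0, nth=48, nz=25) -> TriangleMesh:
    th = np.linspace(0, 2 * np.pi, nth, endpoint=False)
    zz = np.linspace(-height / 2, height / 2, nz)
    V = [
        [radius * np.cos(t), radius * np.sin(t), z] for z in zz for t in th
    ]
    F = []

    def vid(k, i):
        return k * nth + (i % nth)

    for k in range(nz - 1):
        for i in range(nth):
            F.append([vid(k, i), vid(k, i + 1), vid(k + 1, i)])
            F.append([vid(k, i + 1), vid(k + 1, i + 1), vid(k + 1, i)])
    return TriangleMesh(vertices=np.asarray(V), faces=np.asarray(F))


def gradient_volume(axis: str, shape=(30, 32, 34), spacing=(1.0, 1.0, 1.0)):
    """Single-channel volume whose intensity equals one physical coordinate."""
    nz, ny, nx = shape
    dz, dy, dx = spacing
    zz, yy, xx = np.meshgrid(
        np.arange(nz) * dz, np.arange(ny) * dy, np.arange(nx) * dx, indexing="ij"
    )
    data = {"x": xx, "y": yy, "z": zz}[axis]
    return VolumetricImage(data=data[None].astype(float), spacing=spacing)


@pytest.fixture(scope="session")
def sphere_shell():
    """Shell fixture around a 20 μm sphere (image, mask, ground truth)."""
    return make_shell_volume(Sphere(20.0), spacing=1.0, shell_thickness=2.0, seed=7)
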