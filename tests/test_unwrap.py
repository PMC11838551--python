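"""UV parameterizations: chart projections, seams, flattening, conformal map."""

import numpy as np
import pytest
from scipy.spatial import Delaunay
from scipy.spatial.transform import Rotation

from tissuecarto.analysis import area_distortion
from tissuecarto.mesh import TriangleMesh, remove_unused_vertices
from tissuecarto.synthetic import Ellipsoid, Sphere, make_mesh
from tissuecarto.unwrap import (
    SeamPath,
    conformal_sphere_map,
    cut_mesh_along_seams,
    uv_axis_projection,
    uv_cylindrical,
    uv_harmonic_disk,
    uv_spherical,
)

from conftest import cylinder_mesh, grid_mesh


def corner_angles(points, faces):
    """Per-face corner angles in degrees; works for 2D and 3D points."""
    a, b, c = points[faces[:, 0]], points[faces[:, 1]], points[faces[:, 2]]
    out = []
    for p, q, r in ((a, b, c), (b, c, a), (c, a, b)):
        u, w = q - p, r - p
        cos = np.einsum("ij,ij->i", u, w) / (
            np.linalg.norm(u, axis=1) * np.linalg.norm(w, axis=1)
        )
        out.append(np.degrees(np.arccos(np.clip(cos, -1, 1))))
    return np.stack(out, axis=1)


def seam_faces(uvm, threshold=0.02):
    u3 = uvm.uv_vertices[uvm.uv_faces][:, :, 0]
    return (u3.min(axis=1) < threshold) | (u3.max(axis=1) > 1 - threshold)


class TestAxisProjection:
    def test_flat_mesh_is_isometric_up_to_scale(self):
        mesh = grid_mesh()
        uvm = uv_axis_projection(mesh, [0, 0, 1])
        uvm.validate_uv()
        dist = area_distortion(uvm)
        assert np.abs(dist.ratio - 1).max() < 1e-9

    def test_reversed_axis_mirrored_to_consistent_orientation(self):
        # viewing the sheet from the back (axis −z) gives the raw chart
        # mirrored in u; the orientation convention (outward faces positive
        # in UV) mirrors it back, so both views yield the same oriented map
        mesh = grid_mesh()
        up = uv_axis_projection(mesh, [0, 0, 1])
        down = uv_axis_projection(mesh, [0, 0, -1])
        assert (up.uv_signed_areas() > 0).all()
        assert (down.uv_signed_areas() > 0).all()
        assert np.allclose(up.uv_vertices, down.uv_vertices)

    def test_hemisphere_distortion_grows_toward_equator(self, fine_icosphere):
        hemi_faces = fine_icosphere.faces[
            fine_icosphere.vertices[fine_icosphere.faces].mean(axis=1)[:, 2] > 0.2
        ]
        hemi = remove_unused_vertices(fine_icosphere.vertices, hemi_faces)
        uvm = uv_axis_projection(hemi, [0, 0, 1])
        dist = area_distortion(uvm).raw_ratio()
        z = hemi.vertices[hemi.faces].mean(axis=1)[:, 2]
        polar = dist[z > 0.9].mean()
        equatorial = dist[z < 0.45].mean()
        assert equatorial > 1.5 * polar

    def test_degenerate_axis_errors(self):
        with pytest.raises(ValueError, match="axis"):
            uv_axis_projection(grid_mesh(), [0, 0, 0])


class TestSpherical:
    def test_convention_defining_vertices(self, unit_icosphere):
        uvm = uv_spherical(unit_icosphere)
        i = np.argmin(np.linalg.norm(unit_icosphere.vertices - [1, 0, 0], axis=1))
        assert np.allclose(unit_icosphere.vertices[i], [1, 0, 0], atol=1e-12)
        assert np.allclose(uvm.uv_vertices[i], [0.0, 0.5], atol=1e-12)
        top = np.argmax(unit_icosphere.vertices[:, 2])
        assert uvm.uv_vertices[top, 1] == pytest.approx(1.0)
        assert (uvm.uv_signed_areas() > 0).all()

    def test_area_distortion_proportional_to_sin_colatitude(self, fine_icosphere):
        # lat-long area element r² sinθ dθ dφ ⇒ A3D/AUV ∝ sinθ
        uvm = uv_spherical(fine_icosphere)
        dist = area_distortion(uvm).raw_ratio()
        cen = fine_icosphere.face_centroids()
        colat = np.arccos(cen[:, 2] / np.linalg.norm(cen, axis=1))
        mid = (colat > 0.6) & (colat < np.pi - 0.6) & ~seam_faces(uvm)
        rel = dist[mid] / np.sin(colat[mid])
        rel /= np.median(rel)
        assert np.abs(rel - 1).max() < 0.10

    def test_chart_is_invertible_on_exact_sphere(self, unit_icosphere):
        uvm = uv_spherical(unit_icosphere)
        n = unit_icosphere.n_vertices
        u, v = uvm.uv_vertices[:n, 0], uvm.uv_vertices[:n, 1]
        theta = (1 - v) * np.pi
        phi = u * 2 * np.pi
        back = np.column_stack(
            [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)]
        )
        r = np.linalg.norm(unit_icosphere.vertices, axis=1)
        assert np.abs(back * r[:, None] - unit_icosphere.vertices).max() < 1e-9

    def test_center_on_vertex_errors(self, unit_icosphere):
        with pytest.raises(ValueError, match="center"):
            uv_spherical(unit_icosphere, center=unit_icosphere.vertices[0])

    def test_non_orthogonal_axes_rejected(self, unit_icosphere):
        with pytest.raises(ValueError, match="orthogonal"):
            uv_spherical(unit_icosphere, pole_axis=[0, 0, 1], meridian_axis=[0, 0.1, 1])


class TestCylindrical:
    def test_cylinder_unrolls_with_constant_distortion(self):
        cyl = cylinder_mesh()
        uvm = uv_cylindrical(cyl, [0, 0, 0], [0, 0, 1], [1, 0, 0])
        uvm.validate_uv()
        dist = area_distortion(uvm).ratio[~seam_faces(uvm)]
        assert np.abs(dist / np.median(dist) - 1).max() < 0.05

    def test_convention_vertex(self):
        cyl = cylinder_mesh(nz=25)
        uvm = uv_cylindrical(cyl, [0, 0, 0], [0, 0, 1], [1, 0, 0])
        i = np.argmin(np.linalg.norm(cyl.vertices - [1, 0, 0], axis=1))
        assert np.allclose(uvm.uv_vertices[i], [0.0, 0.5], atol=1e-9)

    def test_sphere_equal_area_archimedes(self, fine_icosphere):
        mesh = fine_icosphere.copy()
        R = Rotation.from_rotvec([0.3, 0.2, 0.1]).as_matrix()
        mesh.vertices = mesh.vertices @ R.T  # avoid poles exactly on the axis
        uvm = uv_cylindrical(mesh, [0, 0, 0], [0, 0, 1], [1, 0, 0])
        colat = np.arccos(
            np.clip(
                mesh.face_centroids()[:, 2]
                / np.linalg.norm(mesh.face_centroids(), axis=1),
                -1, 1,
            )
        )
        mid = (colat > 0.5) & (colat < np.pi - 0.5) & ~seam_faces(uvm)
        ratio = area_distortion(uvm).ratio[mid]
        assert np.abs(ratio / np.median(ratio) - 1).max() < 0.10

    def test_vertex_on_axis_errors(self, unit_icosphere):
        with pytest.raises(ValueError, match="axis"):
            uv_cylindrical(unit_icosphere, [0, 0, 0], [0, 0, 1], [1, 0, 0])


def meridian_path(mesh: TriangleMesh) -> list[int]:
    adj: dict[int, set] = {}
    for e in mesh.edges():
        adj.setdefault(int(e[0]), set()).add(int(e[1]))
        adj.setdefault(int(e[1]), set()).add(int(e[0]))
    cur = int(np.argmax(mesh.vertices[:, 2]))
    goal = int(np.argmin(mesh.vertices[:, 2]))
    path = [cur]
    while cur != goal:
        cur = min(adj[cur], key=lambda v: mesh.vertices[v, 2])
        path.append(cur)
    return path


def torus_mesh(R=2.0, r=0.7, nu=24, nv=16) -> TriangleMesh:
    V = []
    for i in range(nu):
        a = 2 * np.pi * i / nu
        for j in range(nv):
            b = 2 * np.pi * j / nv
            V.append(
                [(R + r * np.cos(b)) * np.cos(a), (R + r * np.cos(b)) * np.sin(a),
                 r * np.sin(b)]
            )
    F = []
    for i in range(nu):
        for j in range(nv):
            a = i * nv + j
            b = i * nv + (j + 1) % nv
            c = ((i + 1) % nu) * nv + j
            d = ((i + 1) % nu) * nv + (j + 1) % nv
            F.append([a, b, d])
            F.append([a, d, c])
    return TriangleMesh(vertices=np.asarray(V), faces=np.asarray(F))


class TestSeamCutting:
    def test_meridian_cut_opens_sphere_to_disk(self, unit_icosphere):
        path = meridian_path(unit_icosphere)
        cut = cut_mesh_along_seams(unit_icosphere, [SeamPath(path)])
        assert cut.euler_characteristic() == 1
        assert len(cut.boundary_edges()) > 0
        assert cut.n_faces == unit_icosphere.n_faces  # geometry unchanged

    def test_empty_seams_on_closed_sphere_error(self, unit_icosphere):
        with pytest.raises(ValueError, match="Euler characteristic 2"):
            cut_mesh_along_seams(unit_icosphere, [])

    def test_torus_two_loops_give_disk(self):
        torus = torus_mesh()
        nv = 16
        meridian = [j for j in range(nv)] + [0]  # poloidal loop at i=0
        longitude = [i * nv for i in range(24)] + [0]  # toroidal loop at j=0
        cut = cut_mesh_along_seams(torus, [SeamPath(meridian), SeamPath(longitude)])
        assert cut.euler_characteristic() == 1

    def test_non_edge_path_rejected(self, unit_icosphere):
        far = [0, unit_icosphere.n_vertices - 1]
        e = set(map(tuple, unit_icosphere.edges()))
        if tuple(sorted(far)) not in e:
            with pytest.raises(ValueError, match="edge"):
                cut_mesh_along_seams(unit_icosphere, [SeamPath(far)])


class TestHarmonicDisk:
    def test_flat_disk_reproduced_up_to_similarity(self):
        pts = [[0.0, 0.0]]
        for r in (0.33, 0.66, 1.0):
            k = int(24 * r)
            for t in np.linspace(0, 2 * np.pi, k, endpoint=False):
                pts.append([r * np.cos(t), r * np.sin(t)])
        pts = np.asarray(pts)
        tri = Delaunay(pts)
        disk = TriangleMesh(
            vertices=np.column_stack([pts, np.zeros(len(pts))]), faces=tri.simplices
        )
        uvm = uv_harmonic_disk(disk)
        a3 = corner_angles(pts, disk.faces)
        a2 = corner_angles(uvm.uv_vertices, uvm.uv_faces)
        boundary = set(np.unique(disk.boundary_edges()))
        interior = ~np.array([any(v in boundary for v in f) for f in disk.faces])
        assert np.abs(a3 - a2)[interior].max() < 1.0

    def test_hemisphere_has_no_flipped_triangles(self, fine_icosphere):
        hemi_faces = fine_icosphere.faces[
            fine_icosphere.vertices[fine_icosphere.faces].mean(axis=1)[:, 2] > 0
        ]
        hemi = remove_unused_vertices(fine_icosphere.vertices, hemi_faces)
        uvm = uv_harmonic_disk(hemi)
        assert (uvm.uv_signed_areas() > 0).all()

    def test_two_triangle_square_boundary_only(self):
        sq = TriangleMesh(
            vertices=np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0.0]]),
            faces=np.array([[0, 1, 2], [0, 2, 3]]),
        )
        uvm = uv_harmonic_disk(sq)
        uvm.validate_uv()
        # 0 interior vertices: positions are exactly the circular boundary map
        assert uvm.uv_vertices.min() >= 0.01 - 1e-12
        assert uvm.uv_vertices.max() <= 0.99 + 1e-12

    def test_closed_mesh_rejected(self, unit_icosphere):
        with pytest.raises(ValueError, match="disk"):
            uv_harmonic_disk(unit_icosphere)


class TestConformalSphereMap:
    def test_icosphere_maps_to_own_directions(self, unit_icosphere):
        s = conformal_sphere_map(unit_icosphere)
        assert np.abs(np.linalg.norm(s, axis=1) - 1).max() < 1e-9
        d = unit_icosphere.vertices / np.linalg.norm(
            unit_icosphere.vertices, axis=1, keepdims=True
        )
        from tissuecarto.alignment import procrustes

        T = procrustes(s, d, allow_scale=False)
        assert np.linalg.norm(T.apply(s) - d, axis=1).max() < 1e-3

    def test_ellipsoid_is_conformal_but_not_equiareal(self, ellipsoid_211):
        s = conformal_sphere_map(ellipsoid_211)
        sm = TriangleMesh(vertices=s, faces=ellipsoid_211.faces)
        da = np.abs(
            corner_angles(ellipsoid_211.vertices, ellipsoid_211.faces)
            - corner_angles(s, sm.faces)
        )
        assert np.median(da) < 2.0
        ratio = ellipsoid_211.face_areas() / sm.face_areas()
        assert ratio.max() / ratio.min() > 2.0  # area distortion non-constant

    def test_torus_rejected(self):
        with pytest.raises(ValueError, match="genus-0|Euler"):
            conformal_sphere_map(torus_mesh())
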