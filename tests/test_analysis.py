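"""Cartographic distortion, 2D→3D lifting, corrected areas, surface calculus."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tissuecarto.analysis import (
    area_distortion,
    corrected_label_areas,
    decompose_field,
    laplacian_of,
    surface_curl,
    surface_divergence,
    surface_gradient,
    uv_points_to_3d,
)
from tissuecarto.mesh import lumped_mass
from tissuecarto.projection import pixel_centers_uv, pullback, rasterize_uv
from tissuecarto.synthetic import Sphere, make_mesh
from tissuecarto.unwrap import uv_spherical

from conftest import flat_uv_mesh, gradient_volume


class TestAreaDistortion:
    def test_flat_chart_is_unity(self, flat_chart):
        dist = area_distortion(flat_chart)
        assert np.abs(dist.ratio - 1).max() < 1e-9

    def test_normalization_weighted_mean_is_one(self, fine_icosphere):
        uvm = uv_spherical(fine_icosphere)
        dist = area_distortion(uvm)
        auv = np.abs(uvm.uv_signed_areas())
        assert (dist.ratio * auv).sum() / auv.sum() == pytest.approx(1.0, abs=1e-9)

    def test_invariant_under_uv_similarity(self, flat_chart):
        dist0 = area_distortion(flat_chart).ratio
        scaled = flat_chart.copy()
        scaled.uv_vertices = scaled.uv_vertices * 0.5 + 0.25
        dist1 = area_distortion(scaled).ratio
        assert np.abs(dist0 - dist1).max() < 1e-9

    def test_raster_converges_under_subdivision(self):
        # per-face constant distortion converges first order in mesh size:
        # the raster difference between refinement levels roughly halves
        rasters = {}
        for sub in (2, 3, 4, 5):
            mesh = make_mesh(Sphere(1.0), sub)
            uvm = uv_spherical(mesh)
            rasters[sub] = area_distortion(uvm, grid_shape=(128, 128)).raster

        def rms(a, b):
            both = (a > 0) & (b > 0)
            both[:16] = both[-16:] = False  # pole rows compare chart slivers
            d = a[both] - b[both]
            return np.sqrt(np.mean(d**2)) / np.mean(b[both])

        steps = [rms(rasters[2], rasters[3]), rms(rasters[3], rasters[4]),
                 rms(rasters[4], rasters[5])]
        assert steps[1] < 0.8 * steps[0]
        assert steps[2] < 0.8 * steps[1]
        assert steps[2] < 0.05

    def test_zero_area_uv_face_errors(self, flat_chart):
        broken = flat_chart.copy()
        broken.uv_vertices[broken.uv_faces[0]] = [0.5, 0.5]
        with pytest.raises(ValueError, match="zero-area UV face"):
            area_distortion(broken)


class TestUVLift:
    def test_uv_vertices_are_fixed_points(self, flat_chart):
        pos, _, ok = uv_points_to_3d(flat_chart, flat_chart.uv_vertices)
        assert ok.all()
        assert np.abs(pos - flat_chart.vertices).max() < 1e-12

    def test_matches_pullback_positions(self, fine_icosphere):
        uvm = uv_spherical(fine_icosphere)
        img = gradient_volume("x", shape=(8, 8, 8))
        proj = pullback(img, uvm, (64, 64))
        u, v = pixel_centers_uv((64, 64))
        U, Vv = np.meshgrid(u, v)
        pts = np.column_stack([U.ravel(), Vv.ravel()])
        pos, _, ok = uv_points_to_3d(uvm, pts)
        sel = ok & proj.valid.ravel()
        stacked = np.stack([proj.positions[d].ravel()[sel] for d in range(3)], -1)
        assert np.abs(stacked - pos[sel]).max() < 1e-9

    def test_background_flagged_invalid(self):
        mesh = flat_uv_mesh()
        mesh.uv_vertices = mesh.uv_vertices * 0.5  # chart covers [0, 0.5]²
        _, _, ok = uv_points_to_3d(mesh, np.array([[0.9, 0.9]]))
        assert not ok[0]


class TestCorrectedAreas:
    def test_spherical_cap_label_area(self):
        R = 20.0
        mesh = make_mesh(Sphere(R), 4)
        uvm = uv_spherical(mesh)
        rows = cols = 256
        u, v = pixel_centers_uv((rows, cols))
        U, Vv = np.meshgrid(u, v)
        colat_max = np.radians(30.0)
        labels = (Vv > 1 - colat_max / np.pi).astype(np.int32)  # cap at +pole
        df = corrected_label_areas(labels, uvm)
        cap = df[df.label == 1].iloc[0]
        expected = 2 * np.pi * R**2 * (1 - np.cos(colat_max))
        assert cap.area_3d_um2 == pytest.approx(expected, rel=0.03)
        # uncorrected area misses by the Jacobian factor
        naive = cap.area_uv * area_distortion(uvm).scale
        assert abs(naive / expected - 1) > 0.25

    def test_full_surface_label_recovers_total_area(self, fine_icosphere):
        uvm = uv_spherical(fine_icosphere)
        labels = np.ones((256, 256), np.int32)
        df = corrected_label_areas(labels, uvm)
        assert df.area_3d_um2.iloc[0] == pytest.approx(fine_icosphere.area(), rel=0.02)

    def test_flat_chart_area_is_scaled_pixel_count(self, flat_chart):
        labels = np.zeros((64, 64), np.int32)
        labels[10:20, 12:30] = 1
        df = corrected_label_areas(labels, flat_chart)
        row = df.iloc[0]
        scale = area_distortion(flat_chart).scale  # (100 μm)² per unit UV
        assert row.area_3d_um2 == pytest.approx(row.area_uv * scale, rel=1e-9)

    def test_label_outside_chart_warns(self):
        mesh = flat_uv_mesh()
        mesh.uv_vertices = mesh.uv_vertices * 0.5
        labels = np.zeros((64, 64), np.int32)
        labels[:, :] = 1  # half the label is off-chart
        with pytest.warns(UserWarning, match="invalid"):
            corrected_label_areas(labels, mesh)


class TestDecompose:
    def test_normal_field_has_zero_tangential_part(self, unit_icosphere):
        n = unit_icosphere.face_normals()
        tf, vn = decompose_field(unit_icosphere, n)
        assert np.abs(tf.vectors).max() < 1e-12
        assert np.abs(vn - 1).max() < 1e-12

    def test_inplane_field_on_flat_mesh(self, flat_chart):
        field = np.tile([1.0, 0.0, 0.0], (flat_chart.n_faces, 1))
        tf, vn = decompose_field(flat_chart, field)
        assert np.abs(tf.vectors - field).max() < 1e-12
        assert np.abs(vn).max() < 1e-12

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_reconstruction_identity(self, unit_icosphere, seed):
        rng = np.random.default_rng(seed)
        field = rng.normal(size=(unit_icosphere.n_faces, 3))
        tf, vn = decompose_field(unit_icosphere, field)
        n = unit_icosphere.face_normals()
        recon = tf.vectors + vn[:, None] * n
        assert np.abs(recon - field).max() < 1e-12
        assert tf.residual.max() < 1e-9


class TestSurfaceCalculus:
    def test_gradient_exact_on_linear_functions(self, flat_chart):
        a = np.array([0.3, -0.7, 0.0])
        f = flat_chart.vertices @ a
        g = surface_gradient(flat_chart, f)
        assert np.abs(g.vectors - a).max() < 1e-12

    def test_gradient_of_z_on_sphere(self, fine_icosphere):
        g = surface_gradient(fine_icosphere, fine_icosphere.vertices[:, 2])
        cen = fine_icosphere.face_centroids()
        colat = np.arccos(np.clip(cen[:, 2] / np.linalg.norm(cen, axis=1), -1, 1))
        mags = np.linalg.norm(g.vectors, axis=1)
        mid = (colat > 0.4) & (colat < np.pi - 0.4)
        assert np.abs(mags[mid] / np.sin(colat[mid]) - 1).max() < 0.05

    def test_constant_function_zero_gradient(self, unit_icosphere):
        g = surface_gradient(unit_icosphere, np.full(unit_icosphere.n_vertices, 3.5))
        assert np.abs(g.vectors).max() < 1e-12

    def test_divergence_of_gradient_is_laplacian(self, fine_icosphere):
        f = fine_icosphere.vertices[:, 2] ** 2 - fine_icosphere.vertices[:, 0]
        g = surface_gradient(fine_icosphere, f)
        div = surface_divergence(fine_icosphere, g)
        lap = laplacian_of(fine_icosphere, f)
        assert np.abs(div - lap).max() < 1e-9
        M = lumped_mass(fine_icosphere)
        assert abs((M * div).sum()) < 1e-9  # discrete divergence theorem

    def test_zero_field_zero_divergence_and_curl(self, unit_icosphere):
        zero = np.zeros((unit_icosphere.n_faces, 3))
        assert np.abs(surface_divergence(unit_icosphere, zero)).max() == 0
        assert np.abs(surface_curl(unit_icosphere, zero)).max() == 0

    def test_rotation_field_divergence_free(self, fine_icosphere):
        cen = fine_icosphere.face_centroids()
        field = np.cross(np.array([0, 0, 1.0]), cen)
        tf, _ = decompose_field(fine_icosphere, field)
        div = surface_divergence(fine_icosphere, tf)
        M = lumped_mass(fine_icosphere)
        rms = np.sqrt((M * div**2).sum() / M.sum())
        assert rms < 0.05  # analytic divergence of a Killing field is 0

    def test_curl_of_gradient_vanishes(self, fine_icosphere):
        f = np.sin(fine_icosphere.vertices[:, 0]) + fine_icosphere.vertices[:, 1]
        g = surface_gradient(fine_icosphere, f)
        curl = surface_curl(fine_icosphere, g)
        M = lumped_mass(fine_icosphere)
        assert np.sqrt((M * curl**2).sum() / M.sum()) < 1e-9

    def test_curl_of_rotation_field_matches_analytic(self, fine_icosphere):
        cen = fine_icosphere.face_centroids()
        field = np.cross(np.array([0, 0, 1.0]), cen)
        tf, _ = decompose_field(fine_icosphere, field)
        curl = surface_curl(fine_icosphere, tf)
        z = fine_icosphere.vertices[:, 2]
        mid = np.abs(z) < 0.7
        rel = np.abs(curl[mid] - 2 * z[mid]) / 2.0
        assert np.median(rel) < 0.05
        assert rel.max() < 0.10

    def test_non_tangent_field_rejected(self, unit_icosphere):
        n = unit_icosphere.face_normals()
        with pytest.raises(ValueError, match="decompose"):
            surface_divergence(unit_icosphere, n)

    def test_count_mismatch_rejected(self, unit_icosphere):
        with pytest.raises(ValueError, match="per face|per vertex"):
            decompose_field(unit_icosphere, np.zeros((3, 3)))
        with pytest.raises(ValueError, match="per vertex"):
            surface_gradient(unit_icosphere, np.zeros(5))
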