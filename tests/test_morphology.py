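"""Volumetry and curvature estimation against analytic oracles."""
import numpy as np
import pytest

import organmorph as om
from organmorph.core import VoxelVolume
from organmorph.errors import DegenerateError, EmptyInputError, ParameterError


class TestComputeVolume:
    def test_unit_block(self):
        data = np.zeros((12, 12, 12), dtype=np.uint8)
        data[1:11, 1:11, 1:11] = 1
        assert om.compute_volume(VoxelVolume(data, (1, 1, 1))) == pytest.approx(1.0)

    def test_anisotropic_mri_spacing(self):
        # 10 000 voxels at the pancreas-protocol spacing
        data = np.zeros((25, 25, 16), dtype=np.uint8)
        data.ravel()[:10000] = 1
        np.random.default_rng(0).shuffle(data.ravel())
        vol = VoxelVolume(data, (1.3128, 1.3128, 2.0))
        assert om.compute_volume(vol) == pytest.approx(10000 * 1.3128**2 * 2.0 / 1000.0)

    def test_sphere_within_2_percent(self, sphere20):
        vol, _ = sphere20
        assert om.compute_volume(vol) == pytest.approx(33.5103, rel=0.02)

    def test_empty_mask_returns_zero(self):
        vol = VoxelVolume(np.zeros((4, 4, 4), dtype=np.uint8), (1, 1, 1))
        assert om.compute_volume(vol) == 0.0


class TestVertexNormals:
    def test_tetrahedron_normals_radial(self, tetrahedron):
        normals = om.vertex_normals(tetrahedron)
        expected = tetrahedron.vertices / np.linalg.norm(
            tetrahedron.vertices, axis=1, keepdims=True
        )
        assert np.allclose(normals, expected, atol=1e-12)

    def test_icosphere_normals_within_2_degrees(self, icosphere25):
        normals = om.vertex_normals(icosphere25)
        radial = icosphere25.vertices / np.linalg.norm(
            icosphere25.vertices, axis=1, keepdims=True
        )
        cosang = np.einsum("ij,ij->i", normals, radial)
        assert np.all(np.degrees(np.arccos(np.clip(cosang, -1, 1))) < 2.0)

    def test_flat_patch_normal_exact(self, flat_patch):
        mesh, n = flat_patch
        normals = om.vertex_normals(mesh)
        interior = n * (n // 2) + n // 2
        assert np.allclose(np.abs(normals[interior]), [0, 0, 1], atol=1e-12)

    def test_unit_length(self, sphere20_mesh):
        normals = om.vertex_normals(sphere20_mesh)
        assert np.allclose(np.linalg.norm(normals, axis=1), 1.0, atol=1e-9)


class TestSelectNeighbours:
    def test_matches_brute_force_sort(self, icosphere25):
        mesh = icosphere25
        for vi in (0, 17, 101):
            d = np.linalg.norm(mesh.vertices - mesh.vertices[vi], axis=1)
            d[vi] = np.inf
            expected = np.argsort(d, kind="stable")[:5]
            got = om.select_neighbours(mesh, vi, 5)
            assert set(got) == set(expected)
            assert vi not in got

    def test_k_too_large(self, tetrahedron):
        with pytest.raises(ParameterError):
            om.select_neighbours(tetrahedron, 0, 4)


class TestDirectionalCurvature:
    def test_sphere_pairs_exact(self):
        rng = np.random.default_rng(3)
        for radius in (5.0, 25.0, 250.0):
            for _ in range(20):
                q, qi = rng.normal(size=(2, 3))
                q = q / np.linalg.norm(q) * radius
                qi = qi / np.linalg.norm(qi) * radius
                c = om.directional_curvature(q, q / radius, qi, qi / radius)
                assert c == pytest.approx(-1.0 / radius, rel=1e-12)

    def test_plane_is_flat(self):
        n = np.array([0.0, 0.0, 1.0])
        c = om.directional_curvature(
            np.array([0.0, 0, 0]), n, np.array([3.0, 1.0, 0.0]), n
        )
        assert c == 0.0

    def test_coincident_points_rejected(self):
        n = np.array([0.0, 0.0, 1.0])
        with pytest.raises(DegenerateError):
            om.directional_curvature(np.zeros(3), n, np.zeros(3), n)

    def test_neighbour_along_normal_rejected(self):
        n = np.array([0.0, 0.0, 1.0])
        with pytest.raises(DegenerateError):
            om.directional_curvature(np.zeros(3), n, np.array([0.0, 0.0, 2.0]), n)


class TestLocalGlobalCurvature:
    def test_exact_on_analytic_sphere_with_radial_normals(self, icosphere25):
        mesh = icosphere25
        normals = mesh.vertices / np.linalg.norm(mesh.vertices, axis=1, keepdims=True)
        for vi in (0, 33, 999):
            c = om.local_curvature(mesh, normals, vi, 50)
            assert c == pytest.approx(0.04, rel=1e-9)

    def test_flat_patch_interior_zero(self, flat_patch):
        mesh, n = flat_patch
        normals = om.vertex_normals(mesh)
        interior = n * (n // 2) + n // 2
        assert om.local_curvature(mesh, normals, interior, 8) == pytest.approx(0.0, abs=1e-12)

    def test_scale_covariance(self, icosphere25):
        field = om.global_curvature(icosphere25, 30)
        doubled = om.TriMesh(icosphere25.vertices * 2.0, icosphere25.faces)
        field2 = om.global_curvature(doubled, 30)
        assert field2.global_value == pytest.approx(field.global_value / 2.0, rel=1e-9)
        assert np.allclose(field2.local, field.local / 2.0, rtol=1e-9)

    def test_global_is_mean_of_local(self, sphere20_mesh):
        field = om.global_curvature(sphere20_mesh, 50)
        assert field.global_value == pytest.approx(float(field.local.mean()), rel=1e-12)
        assert np.all(field.local >= 0)

    def test_pipeline_sphere_curvature(self):
        vol, _ = om.make_sphere(25.0)
        mesh = om.reconstruct_organ(vol)
        field = om.global_curvature(mesh, 50)
        assert field.global_value == pytest.approx(0.04, rel=0.10)

    def test_variance_non_increasing_in_k(self):
        vol, _ = om.make_lobed_blob(20.0, 0.2, seed=4)
        mesh = om.reconstruct_organ(vol)
        variances = [
            float(np.var(om.global_curvature(mesh, k).local)) for k in (10, 25, 50, 100)
        ]
        assert all(b <= a * 1.0 + 1e-15 for a, b in zip(variances, variances[1:]))


class TestCurvatureBands:
    def test_band_arithmetic(self):
        field = om.CurvatureField(
            local=np.array([0.1, 0.2, 0.4]),
            global_value=0.7 / 3,
            neighbourhood_size=2,
            normals=np.tile([0.0, 0, 1], (3, 1)),
        )
        assert om.curvature_bands(field, 0.25).tolist() == [1, 2, 3]

    def test_constant_field_top_band(self):
        field = om.CurvatureField(
            local=np.full(4, 0.3), global_value=0.3, neighbourhood_size=2,
            normals=np.tile([0.0, 0, 1], (4, 1)),
        )
        bands = om.curvature_bands(field, 0.05)
        assert np.all(bands == 19)

    def test_zero_field_single_band(self):
        field = om.CurvatureField(
            local=np.zeros(4), global_value=0.0, neighbourhood_size=2,
            normals=np.tile([0.0, 0, 1], (4, 1)),
        )
        assert np.all(om.curvature_bands(field, 0.05) == 0)

    def test_band_count_bounded(self, sphere20_mesh):
        field = om.global_curvature(sphere20_mesh, 50)
        for w in (0.05, 0.25, 0.3):
            bands = om.curvature_bands(field, w)
            assert len(np.unique(bands)) <= int(np.ceil(1 / w)) + 1


class TestMeasureCase:
    def test_sphere_report(self, sphere20):
        vol, _ = sphere20
        report = om.measure_case(vol, case_id="s20")
        assert report.volume_cm3 == pytest.approx(33.5103, rel=0.02)
        assert report.global_curvature == pytest.approx(0.05, rel=0.10)
        assert report.vertex_count > 100

    def test_deterministic(self, sphere20):
        vol, _ = sphere20
        a = om.measure_case(vol)
        b = om.measure_case(vol)
        assert a.volume_cm3 == b.volume_cm3
        assert a.global_curvature == b.global_curvature

    def test_empty_mask_rejected(self):
        vol = VoxelVolume(np.zeros((4, 4, 4), dtype=np.uint8), (1, 1, 1))
        with pytest.raises(EmptyInputError):
            om.measure_case(vol)
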