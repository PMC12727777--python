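import numpy as np
import pytest
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from conftest import grid_plane, random_point_mesh
from microdomain3d.io_volumes import SeedPointSet
from microdomain3d.contacts import (
    asd,
    distance_map_export,
    mam_patches,
    proximity_events,
    read_distance_map,
    total_contact_area,
)
from microdomain3d.meshing import SurfaceMesh


def brute_force_asd(pm: SurfaceMesh, er: SurfaceMesh) -> float:
    """O(n*m) all-pairs oracle for the mean nearest-vertex distance."""
    return float(cdist(pm.vertices, er.vertices).min(axis=1).mean())


class TestASD:
    def test_identical_meshes_give_zero(self):
        mesh = grid_plane(200.0, 20.0)
        assert asd(mesh, mesh).asd == 0.0

    def test_parallel_aligned_planes_exact_gap(self):
        pm = grid_plane(500.0, 20.0, z=0.0)
        er = grid_plane(500.0, 20.0, z=100.0)
        res = asd(pm, er)
        assert res.asd == pytest.approx(100.0, rel=1e-12)
        assert np.allclose(res.per_vertex_distances, 100.0)
        assert res.n_vertices == pm.n_vertices

    def test_mean_is_exact_mean_of_per_vertex(self):
        rng = np.random.default_rng(3)
        res = asd(random_point_mesh(rng, 200), random_point_mesh(rng, 150, offset=(50, 0, 0)))
        assert res.asd == pytest.approx(res.per_vertex_distances.mean(), abs=0)
        assert res.asd <= res.per_vertex_distances.max()
        assert (res.per_vertex_distances >= 0).all()

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            pm = random_point_mesh(rng, rng.integers(50, 300))
            er = random_point_mesh(rng, rng.integers(50, 300), offset=(80, -20, 10))
            assert asd(pm, er).asd == pytest.approx(brute_force_asd(pm, er), rel=1e-12)

    def test_one_directional_not_symmetric(self):
        rng = np.random.default_rng(5)
        pm = random_point_mesh(rng, 100, scale=50.0)
        er = random_point_mesh(rng, 400, scale=200.0)
        assert asd(pm, er).asd != pytest.approx(asd(er, pm).asd, rel=1e-3)

    def test_empty_side_identified_in_error(self):
        mesh = grid_plane(100.0, 20.0)
        with pytest.raises(ValueError, match="ER"):
            asd(mesh, SurfaceMesh.empty())
        with pytest.raises(ValueError, match="PM"):
            asd(SurfaceMesh.empty(), mesh)

    def test_rigid_transform_invariance(self):
        rng = np.random.default_rng(11)
        pm = random_point_mesh(rng, 150)
        er = random_point_mesh(rng, 180, offset=(60, 0, 0))
        base = asd(pm, er).asd
        for _ in range(5):
            R = Rotation.random(random_state=rng).as_matrix()
            t = rng.normal(size=3) * 500
            pm2 = SurfaceMesh(pm.vertices @ R.T + t, pm.faces)
            er2 = SurfaceMesh(er.vertices @ R.T + t, er.faces)
            assert asd(pm2, er2).asd == pytest.approx(base, rel=1e-6)

    def test_refining_target_never_increases_distances(self):
        """Adding ER vertices (superset) can only shrink each per-vertex distance."""
        rng = np.random.default_rng(13)
        pm = random_point_mesh(rng, 120)
        er_coarse = random_point_mesh(rng, 100, offset=(70, 0, 0))
        extra = random_point_mesh(rng, 200, offset=(70, 0, 0))
        er_fine = SurfaceMesh(np.vstack([er_coarse.vertices, extra.vertices]), np.empty((0, 3), int))
        d_coarse = asd(pm, er_coarse).per_vertex_distances
        d_fine = asd(pm, er_fine).per_vertex_distances
        assert (d_fine <= d_coarse + 1e-12).all()

    def test_surface_mode_is_lower_bound_of_vertex_mode(self):
        pm = grid_plane(200.0, 40.0, z=0.0)
        # larger ER plane, shifted laterally by half a cell so vertices no
        # longer align and every PM vertex projects onto the ER interior
        er = grid_plane(320.0, 40.0, z=100.0)
        er = SurfaceMesh(er.vertices + np.array([20.0, 20.0, 0.0]), er.faces)
        v = asd(pm, er, mode="vertex").per_vertex_distances
        s = asd(pm, er, mode="surface").per_vertex_distances
        assert (s <= v + 1e-9).all()
        assert s.mean() == pytest.approx(100.0, rel=1e-6)  # point-to-plane


class TestProximityEvents:
    def test_planes_above_threshold_no_events(self):
        pm = grid_plane(500.0, 20.0, z=0.0)
        er = grid_plane(500.0, 20.0, z=100.0)
        assert proximity_events(pm, er, 20.0) == []

    def _dimpled_plane(self):
        pm = grid_plane(500.0, 20.0, z=0.0)
        v = pm.vertices.copy()
        close = np.linalg.norm(v[:, :2] - [200.0, 200.0], axis=1) < 50.0
        v[close, 2] = 85.0  # 15 nm from the ER plane at z = 100
        return SurfaceMesh(v, pm.faces), grid_plane(500.0, 20.0, z=100.0), close

    def test_dimple_gives_exactly_one_event(self):
        pm, er, close = self._dimpled_plane()
        events = proximity_events(pm, er, 20.0)
        assert len(events) == 1
        assert events[0].distance_nm == pytest.approx(15.0)
        assert events[0].n_vertices == int(close.sum())

    def test_near_caveola_flag_uses_neighbourhood(self):
        pm, er, _ = self._dimpled_plane()
        seeds_near = SeedPointSet(np.array([[250.0, 250.0, 0.0]]))
        seeds_far = SeedPointSet(np.array([[450.0, -450.0, 0.0]]))
        assert proximity_events(pm, er, 20.0, seeds_near, 200.0)[0].near_caveola
        assert not proximity_events(pm, er, 20.0, seeds_far, 200.0)[0].near_caveola

    def test_two_separate_dimples_two_events(self):
        pm = grid_plane(500.0, 20.0, z=0.0)
        v = pm.vertices.copy()
        for cx in (-300.0, 300.0):
            v[np.linalg.norm(v[:, :2] - [cx, 0.0], axis=1) < 40.0, 2] = 90.0
        events = proximity_events(SurfaceMesh(v, pm.faces), grid_plane(500.0, 20.0, z=100.0), 20.0)
        assert len(events) == 2


class TestMAMPatches:
    def _facet_fixture(self, gap, facet=100.0, pitch=5.0):
        """A flat square mito facet 'facet' nm wide facing a much larger ER plane."""
        mito = grid_plane(facet / 2, pitch, z=gap, role="MITO")
        er = grid_plane(200.0, pitch, z=0.0, role="ER")
        return mito, er

    def test_flat_facet_area_recovered(self):
        # 100 x 100 nm facet at 5 nm gap: one patch, area within 10% of 1e4 nm^2
        mito, er = self._facet_fixture(gap=5.0)
        patches = mam_patches(mito, er, 20.0)
        assert len(patches) == 1
        assert patches[0].area_nm2 == pytest.approx(1e4, rel=0.10)

    def test_gap_above_threshold_no_patches(self):
        mito, er = self._facet_fixture(gap=25.0)
        assert mam_patches(mito, er, 20.0) == []

    def test_empty_er_gives_no_patches_not_error(self):
        mito, _ = self._facet_fixture(gap=5.0)
        assert mam_patches(mito, SurfaceMesh.empty()) == []

    def test_empty_mito_is_an_error(self):
        _, er = self._facet_fixture(gap=5.0)
        with pytest.raises(ValueError, match="mito"):
            mam_patches(SurfaceMesh.empty(), er)

    def test_area_monotone_in_threshold(self):
        """A tilted facet crosses the threshold gradually: area grows with it."""
        mito = grid_plane(150.0, 5.0, z=0.0)
        v = mito.vertices.copy()
        v[:, 2] = 10.0 + 0.15 * (v[:, 0] + 150.0)  # gap rises 10 -> 55 nm across the facet
        mito = SurfaceMesh(v, mito.faces, "MITO")
        er = grid_plane(300.0, 5.0, z=0.0, role="ER")
        areas = [total_contact_area(mam_patches(mito, er, thr)) for thr in (12, 16, 20, 30, 45)]
        assert all(a <= b + 1e-9 for a, b in zip(areas, areas[1:]))
        assert areas[0] < areas[-1]

    def test_patch_area_bounded_by_source_area(self):
        mito, er = self._facet_fixture(gap=5.0)
        assert total_contact_area(mam_patches(mito, er, 20.0)) <= mito.area_nm2 + 1e-9

    def test_sphere_against_plane_matches_spherical_cap(self):
        """Mito sphere (R=200) at 10 nm gap: patch area ~ analytic cap 2*pi*R*h."""
        import trimesh

        R, gap, thr = 200.0, 10.0, 20.0
        ico = trimesh.creation.icosphere(subdivisions=5, radius=R)
        mito = SurfaceMesh(ico.vertices + np.array([0.0, 0.0, R + gap]), ico.faces, "MITO")
        er = grid_plane(300.0, 2.5, z=0.0, role="ER")
        area = total_contact_area(mam_patches(mito, er, thr))
        h = thr - gap  # cap height: sphere points with z < thr
        assert area == pytest.approx(2 * np.pi * R * h, rel=0.10)


class TestDistanceMapExport:
    def test_round_trip_preserves_scalars(self, tmp_path):
        pm = grid_plane(200.0, 20.0, z=0.0)
        er = grid_plane(200.0, 20.0, z=100.0)
        res = asd(pm, er)
        path = tmp_path / "dist.ply"
        distance_map_export(res, pm, path)
        mesh, q = read_distance_map(path)
        assert np.allclose(q, res.per_vertex_distances)
        assert np.allclose(mesh.vertices, pm.vertices)
        assert np.array_equal(mesh.faces, pm.faces)

    def test_identical_meshes_export_zeros(self, tmp_path):
        pm = grid_plane(100.0, 20.0)
        res = asd(pm, pm)
        path = tmp_path / "zero.ply"
        distance_map_export(res, pm, path)
        _, q = read_distance_map(path)
        assert np.allclose(q, 0.0)

    def test_mismatched_result_rejected(self, tmp_path):
        pm = grid_plane(100.0, 20.0)
        other = grid_plane(100.0, 50.0)
        res = asd(other, pm)
        with pytest.raises(ValueError, match="vertex count"):
            distance_map_export(res, pm, tmp_path / "bad.ply")
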