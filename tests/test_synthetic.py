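import numpy as np
import pytest
from scipy import ndimage

from microdomain3d.io_volumes import VoxelSpacing, extract_caveola_seeds
from microdomain3d.microdomain import SphereROI, crop_label_counts
from microdomain3d.synthetic import (
    ICC,
    PDGFRA,
    SMC,
    PhantomSpec,
    generate_paper_scale_scene,
    generate_phantom,
)

SIX = ndimage.generate_binary_structure(3, 1)


class TestDeterminismAndValidation:
    def test_same_spec_and_seed_identical_volumes(self):
        spec = PhantomSpec(archetype=ICC, rng_seed=5, jitter_facets=True)
        v1, g1 = generate_phantom(spec)
        v2, g2 = generate_phantom(spec)
        assert np.array_equal(v1.data, v2.data)
        assert g1.true_volumes == g2.true_volumes
        assert np.array_equal(g1.caveola_centres.points, g2.caveola_centres.points)

    def test_unresolvable_gap_rejected(self):
        with pytest.raises(ValueError, match="er_pm_gap"):
            generate_phantom(PhantomSpec(er_pm_gap=30.0, spacing=VoxelSpacing(10, 10, 20)))

    def test_off_grid_mito_gap_rejected(self):
        with pytest.raises(ValueError, match="mito_er_gap"):
            generate_phantom(PhantomSpec(archetype=ICC, mito_er_gap=13.0))

    def test_unresolvable_caveola_rejected(self):
        with pytest.raises(ValueError, match="caveola"):
            generate_phantom(
                PhantomSpec(caveola_bulb_radius=25.0, spacing=VoxelSpacing(15, 15, 20), mito_count=0)
            )

    def test_unknown_archetype_rejected(self):
        with pytest.raises(ValueError, match="archetype"):
            generate_phantom(PhantomSpec(archetype="HELA"))


class TestGroundTruthVolumes:
    def test_rasterised_volumes_match_analytic(self, icc_phantom):
        vol, gt = icc_phantom
        for role, true_v in gt.true_volumes.items():
            raster = vol.role_mask(role).sum() * vol.spacing.voxel_volume_nm3
            assert raster == pytest.approx(true_v, rel=0.05), role

    def test_volume_match_improves_at_finer_spacing(self):
        def mito_err(spacing):
            vol, gt = generate_phantom(
                PhantomSpec(archetype=ICC, spacing=VoxelSpacing(*spacing), rng_seed=1,
                            interior_lattice=False)
            )
            raster = vol.role_mask("MITO").sum() * vol.spacing.voxel_volume_nm3
            return abs(raster - gt.true_volumes["MITO"]) / gt.true_volumes["MITO"]

        assert mito_err((5, 5, 10)) < mito_err((10, 10, 20))

    def test_mam_facet_area_recorded_only_below_threshold(self):
        _, gt_contact = generate_phantom(PhantomSpec(archetype=ICC, mito_er_gap=10.0, rng_seed=0))
        _, gt_far = generate_phantom(PhantomSpec(archetype=ICC, mito_er_gap=30.0, rng_seed=0))
        assert gt_contact.true_mam_area_per_mito[100] == pytest.approx(6e4)
        assert gt_far.true_mam_area_per_mito[100] == 0.0


class TestArchetypeTopology:
    def test_icc_er_single_connected_component(self, icc_phantom):
        vol, _ = icc_phantom
        _, n = ndimage.label(vol.role_mask("ER"), structure=SIX)
        assert n == 1

    def test_smc_peripheral_strands_pairwise_disconnected(self):
        spec = PhantomSpec(archetype=SMC, rng_seed=2)
        vol, _ = generate_phantom(spec)
        comp, n = ndimage.label(vol.role_mask("ER"), structure=SIX)
        # classify components by depth: peripheral strands live within
        # er_pm_gap + er_thickness of the boundary; the perinuclear shell is deep
        nz, ny, nx = vol.shape
        centre = np.array([nx * vol.spacing.dx, ny * vol.spacing.dy, nz * vol.spacing.dz]) / 2
        peripheral = 0
        for c in range(1, n + 1):
            idx = np.argwhere(comp == c)
            pts = np.stack(
                [
                    (idx[:, 2] + 0.5) * vol.spacing.dx,
                    (idx[:, 1] + 0.5) * vol.spacing.dy,
                    (idx[:, 0] + 0.5) * vol.spacing.dz,
                ],
                axis=1,
            )
            rho = np.sqrt((pts[:, 0] - centre[0]) ** 2 + (pts[:, 2] - centre[2]) ** 2)
            if rho.mean() > spec.cell_radius - 2 * spec.er_pm_gap:
                peripheral += 1
        assert peripheral == spec.n_strands
        assert n == spec.n_strands + 1  # plus the perinuclear shell

    def test_pdgfra_sheets_are_parallel_slabs(self):
        spec = PhantomSpec(archetype=PDGFRA, rng_seed=0)
        vol, gt = generate_phantom(spec)
        er = vol.role_mask("ER")
        # every ER voxel column in x belongs to one of the slab position bands
        xs_idx = np.unique(np.argwhere(er)[:, 2])
        xs = (xs_idx + 0.5) * vol.spacing.dx
        centre_x = vol.shape[2] * vol.spacing.dx / 2
        offsets = (xs - centre_x) / spec.sheet_pitch
        assert np.all(np.abs(offsets - np.round(offsets)) < 0.1)
        assert gt.true_volumes["ER"] > 0


class TestPaperScaleScene:
    def test_at_least_nine_caveolae(self, paper_scene):
        vol, gt = paper_scene
        assert len(gt.caveola_centres) >= 9
        assert len(vol.labels_for_role("CAVEOLA")) >= 9

    def test_some_spheres_lack_mitochondria(self, paper_scene):
        vol, gt = paper_scene
        counts = [
            crop_label_counts(vol, SphereROI(tuple(p), 400.0)).get("MITO", 0)
            for p in gt.caveola_centres.points
        ]
        assert any(c == 0 for c in counts) and any(c > 0 for c in counts)
        # presence matches the generator's own bookkeeping
        assert [c > 0 for c in counts] == gt.mam_positive

    def test_per_sphere_er_ground_truth_in_stated_band(self, paper_scene):
        _, gt = paper_scene
        assert gt.per_sphere_er_volume_nm3 is not None
        assert all(5e6 <= v <= 2.5e7 for v in gt.per_sphere_er_volume_nm3)

    def test_per_sphere_er_ground_truth_close_to_rasterised(self, paper_scene):
        vol, gt = paper_scene
        for p, true_v in zip(gt.caveola_centres.points, gt.per_sphere_er_volume_nm3):
            counts = crop_label_counts(vol, SphereROI(tuple(p), 400.0))
            raster = counts.get("ER", 0) * vol.spacing.voxel_volume_nm3
            assert raster == pytest.approx(true_v, rel=0.05)

    def test_extracted_seeds_near_analytic_centres(self, paper_scene):
        vol, gt = paper_scene
        seeds = extract_caveola_seeds(vol, rng_seed=0, n=9)
        order = np.argsort(seeds.source_labels)
        gt_order = np.argsort(gt.caveola_centres.source_labels)
        d = np.linalg.norm(
            seeds.points[order] - gt.caveola_centres.points[gt_order], axis=1
        )
        # the cup centroid sits near the bulb centre; the flask is ~70 nm deep,
        # so anything within two voxel diagonals identifies the right caveola
        assert (d < 2 * vol.spacing.diagonal_nm).all()
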