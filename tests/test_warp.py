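"""Pseudo-MRI generation, sensor coregistration chaining, parcellation
mapping, medoids and the coregistration-error isolation mode."""

import numpy as np
import pandas as pd
import pytest

from pseudomri import registration as R, synthetic as syn, warp
from pseudomri.geometry import PointCloud, VoxelVolume
from pseudomri.twin import random_rigid
from pseudomri.warp import Parcellation


def mini_parcellation(voxels_by_region, shape=(12, 12, 12), voxel=2.0):
    data = np.zeros(shape, int)
    for rid, vox in voxels_by_region.items():
        for v in vox:
            data[tuple(v)] = rid
    table = pd.DataFrame({"id": sorted(voxels_by_region),
                          "name": [f"r{i}" for i in sorted(voxels_by_region)]})
    return Parcellation(VoxelVolume(data, np.diag([voxel] * 3 + [1.0])), table)


class TestRegionMedoids:
    def test_three_collinear_voxels_give_middle(self):
        parc = mini_parcellation({1: [(2, 2, 2), (2, 2, 4), (2, 2, 6)]})
        med = warp.region_medoids(parc)
        assert np.allclose(med.loc[1, ["x", "y", "z"]], (4.0, 4.0, 8.0))

    def test_symmetric_cross_gives_centre(self):
        parc = mini_parcellation({1: [(5, 5, 5), (4, 5, 5), (6, 5, 5),
                                      (5, 4, 5), (5, 6, 5)]})
        med = warp.region_medoids(parc)
        assert np.allclose(med.loc[1, ["x", "y", "z"]], (10.0, 10.0, 10.0))

    def test_matches_brute_force_on_random_blob(self):
        rng = np.random.default_rng(0)
        vox = list({tuple(v) for v in rng.integers(0, 12, size=(70, 3))})[:50]
        parc = mini_parcellation({1: vox})
        med = warp.region_medoids(parc)
        pts = parc.labels.voxel_to_world(np.argwhere(parc.labels.data == 1))
        dists = np.linalg.norm(pts[:, None] - pts[None], axis=2).sum(axis=1)
        best = pts[np.argmin(dists)]
        assert np.allclose(med.loc[1, ["x", "y", "z"]], best)

    def test_empty_region_recorded_as_missing(self):
        parc = mini_parcellation({1: [(2, 2, 2)]})
        parc.table = pd.concat([parc.table,
                                pd.DataFrame({"id": [2], "name": ["r2"]})],
                               ignore_index=True)
        med = warp.region_medoids(parc)
        assert med.loc[2, "n_voxels"] == 0
        assert np.isnan(med.loc[2, "x"])


class TestMedoidDiscrepancy:
    def table(self, coords):
        return pd.DataFrame(coords, columns=["x", "y", "z"],
                            index=pd.Index(range(1, len(coords) + 1), name="id"))

    def test_identical_gives_zero(self):
        a = self.table(np.random.default_rng(1).uniform(size=(10, 3)))
        per, summary = warp.medoid_discrepancy(a, a)
        assert (per["distance_mm"] == 0).all()
        assert summary["median_mm"] == 0.0

    def test_uniform_shift(self):
        a = self.table(np.random.default_rng(2).uniform(size=(8, 3)))
        b = a + np.array([3.0, 0.0, 0.0])
        per, summary = warp.medoid_discrepancy(a, b)
        assert np.allclose(per["distance_mm"], 3.0)
        assert np.isclose(summary["median_mm"], 3.0)
        assert np.isclose(summary["mad_mm"], 0.0)

    def test_random_jitter_matches_per_region_oracle(self):
        rng = np.random.default_rng(3)
        a = self.table(rng.uniform(0, 50, size=(20, 3)))
        jitter = rng.normal(0, 1.0, size=(20, 3))
        b = a + jitter
        per, summary = warp.medoid_discrepancy(a, b)
        oracle = np.linalg.norm(jitter, axis=1)
        assert np.allclose(per["distance_mm"], oracle)
        assert np.isclose(summary["median_mm"], np.median(oracle))

    def test_id_mismatch_raises(self):
        a = self.table(np.zeros((4, 3)))
        b = a.copy()
        b.index = pd.Index([1, 2, 3, 9], name="id")
        with pytest.raises(ValueError, match="9"):
            warp.medoid_discrepancy(a, b)


@pytest.fixture(scope="module")
def atlas(small_phantom):
    gt = small_phantom
    brain = VoxelVolume(np.asarray(gt.anatomy.data, float)
                        * (np.asarray(gt.brain_mask.data) > 0),
                        gt.anatomy.affine)
    return gt.parcellation, brain


class TestMapParcellation:
    def test_self_mapping_is_near_perfect(self, atlas):
        parc, brain = atlas
        out = warp.map_parcellation(parc, brain, brain)
        a = np.asarray(parc.labels.data)
        b = np.asarray(out.labels.data)
        agree = (a == b).mean()
        assert agree > 0.999

    def test_scaled_subject_scales_region_volumes(self, atlas):
        parc, brain = atlas
        scale = R.AffineTransform(np.diag([1.1, 1.1, 1.1, 1.0]))
        # keep the scaled brain on the same grid (it fits: head is small
        # in this fixture)
        target = VoxelVolume(np.zeros(brain.shape), brain.affine)
        subject = R.resample(brain, scale, target)
        out = warp.map_parcellation(
            parc, brain, subject,
            R.RegistrationConfig(bins=32, domain="support",
                                 boundary_band_vox=2))
        vol_in = (np.asarray(parc.labels.data) > 0).sum()
        vol_out = (np.asarray(out.labels.data) > 0).sum()
        assert abs(vol_out / vol_in - 1.1 ** 3) < 0.05 * 1.1 ** 3

    def test_output_labels_subset_of_table(self, atlas):
        parc, brain = atlas
        out = warp.map_parcellation(parc, brain, brain)
        present = set(np.unique(out.labels.data)) - {0}
        assert present <= set(parc.table["id"])


class TestIsolateCoregistrationError:
    def test_identical_brains_give_identity(self, atlas):
        _, brain = atlas
        T = warp.isolate_coregistration_error(
            brain, brain, R.RegistrationConfig(dof=6, bins=32,
                                               domain="support",
                                               boundary_band_vox=2))
        assert np.abs(T.matrix - np.eye(4)).max() < 0.5  # sub-voxel

    def test_rotation_recovered(self, atlas):
        _, brain = atlas
        rng = np.random.default_rng(5)
        truth = random_rigid(rng, 10.0, 4.0, np.full(3, 94.5))
        target = VoxelVolume(np.zeros(brain.shape), brain.affine)
        moved = R.resample(brain, truth, target)
        T = warp.isolate_coregistration_error(
            brain, moved, R.RegistrationConfig(dof=6, bins=32,
                                               domain="support",
                                               boundary_band_vox=2))
        # compare rotations via the relative angle
        Rrel = T.rotation.T @ truth.rotation
        ang = np.degrees(np.arccos(np.clip((np.trace(Rrel) - 1) / 2, -1, 1)))
        assert ang < 0.5

    def test_output_is_rigid(self, atlas):
        _, brain = atlas
        T = warp.isolate_coregistration_error(brain, brain)
        Rm = T.rotation
        assert isinstance(T, R.RigidTransform)
        assert np.abs(Rm.T @ Rm - np.eye(3)).max() < 1e-9
        assert np.linalg.det(Rm) > 0


class TestGeneratePseudoMRI:
    def test_closed_loop_scan_from_template(self, small_phantom):
        """Scan sampled from the template itself: the pseudo-MRI must
        reproduce the (rigidly moved) template almost exactly."""
        gt = small_phantom
        rng = np.random.default_rng(6)
        centre = gt.scalp.vertices.mean(axis=0)
        D = random_rigid(rng, 8.0, 20.0, centre)
        scan = syn.simulate_headscan(gt.scalp, D, 0.0, None, 0.0, 6000, seed=7)
        res = warp.generate_pseudo_mri(
            gt.anatomy, scan, syn.approximate_fiducials(scan.points),
            syn.approximate_fiducials(gt.scalp.vertices))
        # voxelwise correlation between pseudo-MRI and directly-moved template
        direct = R.resample(gt.anatomy, res.transform, res.pseudo)
        a = np.asarray(res.pseudo.data, float).ravel()
        b = np.asarray(direct.data, float).ravel()
        assert np.corrcoef(a, b)[0, 1] > 0.999
        # and the recovered transform is close to the injected rigid move
        v = gt.scalp.vertices[::9]
        rms = np.sqrt((np.linalg.norm(res.transform.apply(v) - D.apply(v),
                                      axis=1) ** 2).mean())
        assert rms < 2.0

    def test_cropped_scan_still_converges(self, small_phantom):
        gt = small_phantom
        rng = np.random.default_rng(8)
        centre = gt.scalp.vertices.mean(axis=0)
        D = random_rigid(rng, 5.0, 15.0, centre)
        zmin, zmax = gt.scalp.vertices[:, 2].min(), gt.scalp.vertices[:, 2].max()
        plane_pt = D.apply(np.r_[centre[:2], zmin + 0.25 * (zmax - zmin)])[0]
        plane_n = D.apply_vectors(np.array([0.0, 0.0, 1.0]))[0]
        scan = syn.simulate_headscan(gt.scalp, D, 0.5, (plane_pt, plane_n),
                                     0.0, 6000, seed=9)
        res = warp.generate_pseudo_mri(
            gt.anatomy, scan, syn.approximate_fiducials(scan.points),
            syn.approximate_fiducials(gt.scalp.vertices))
        v = gt.scalp.vertices[::9]
        kept = (v - D.apply(plane_pt - 0 * plane_n)[0] @ np.eye(3)) @ plane_n
        # surface error over the retained (upper) head region only
        upper = (D.apply(v) - plane_pt) @ plane_n > 10.0
        rms = np.sqrt((np.linalg.norm(res.transform.apply(v[upper])
                                      - D.apply(v[upper]), axis=1) ** 2).mean())
        assert rms < 4.0

    def test_stage_errors_are_tagged(self, small_phantom):
        gt = small_phantom
        bad_scan = PointCloud(np.zeros((10, 3)))
        with pytest.raises(warp.PipelineStageError):
            warp.generate_pseudo_mri(gt.anatomy, bad_scan,
                                     np.zeros((5, 3)), np.zeros((5, 3)))


class TestChainCoregistration:
    def stages_for(self, gt, transforms):
        """Build a helmet->scan1->scan2->anatomy chain whose stage inputs
        are displaced by the given rigid transforms."""
        cloud = gt.scalp.vertices[::4]
        lm = syn.approximate_fiducials(cloud)
        stages = []
        src_pts, src_lm = cloud, lm
        for name, T in transforms:
            dst_pts = T.apply(src_pts)
            dst_lm = T.apply(src_lm)
            stages.append(warp.CoregStage(
                name, PointCloud(src_pts), PointCloud(dst_pts),
                src_lm, dst_lm))
            src_pts, src_lm = dst_pts, dst_lm
        return stages

    def test_identity_stages_leave_sensors_unchanged(self, small_phantom):
        gt = small_phantom
        sens = syn.place_opm_array(gt.scalp, 16, 6.5, 0)
        eye = R.RigidTransform.identity()
        stages = self.stages_for(gt, [("a", eye), ("b", eye)])
        out, total, _ = warp.chain_sensor_coregistration(sens, stages)
        assert np.abs(out.positions - sens.positions).max() < 1e-6
        assert np.abs(total.matrix - np.eye(4)).max() < 1e-8

    def test_known_perturbations_recovered(self, small_phantom):
        gt = small_phantom
        sens = syn.place_opm_array(gt.scalp, 16, 6.5, 1)
        rng = np.random.default_rng(10)
        c = gt.scalp.vertices.mean(axis=0)
        T1 = random_rigid(rng, 6.0, 10.0, c)
        T2 = random_rigid(rng, 6.0, 10.0, c)
        T3 = random_rigid(rng, 6.0, 10.0, c)
        stages = self.stages_for(gt, [("helmet", T1), ("face", T2),
                                      ("anatomy", T3)])
        out, total, _ = warp.chain_sensor_coregistration(sens, stages)
        truth = R.compose(T3, R.compose(T2, T1))
        pos_err = np.linalg.norm(out.positions - truth.apply(sens.positions),
                                 axis=1)
        assert pos_err.max() < 0.5
        true_ori = truth.apply_vectors(sens.orientations)
        ang = np.degrees(np.arccos(np.clip(np.einsum(
            "ij,ij->i", out.orientations, true_ori), -1, 1)))
        assert ang.max() < 0.5

    def test_orientations_remain_orthonormal_triads(self, small_phantom):
        gt = small_phantom
        sens = syn.place_opm_array(gt.scalp, 16, 6.5, 2)
        rng = np.random.default_rng(11)
        T1 = random_rigid(rng, 15.0, 20.0, gt.scalp.vertices.mean(axis=0))
        stages = self.stages_for(gt, [("only", T1)])
        out, _, _ = warp.chain_sensor_coregistration(sens, stages)
        for sid in np.unique(out.sensor_ids):
            tri = out.orientations[out.sensor_ids == sid]
            assert np.abs(tri @ tri.T - np.eye(3)).max() < 1e-6
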