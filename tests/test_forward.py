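"""Volume-conductor models: sphere fitting, the closed-form spherical
dipole field, the single-shell solver and lead-field assembly.

The spherical dipole field is validated against a fully independent
oracle: the electric surface potential is solved on the conductor
boundary (insulated-Neumann interior problem) and the volume-current
field obtained from the Geselowitz surface integral.
"""

import numpy as np
import pytest
import trimesh
from scipy.special import sph_harm_y

from pseudomri import forward as fw
from pseudomri.forward import (ConductorModel, LeadField, SingleShellModel,
                               SourceSpace, build_leadfield,
                               dipole_field_sphere, fit_sphere)
from pseudomri.geometry import DegenerateGeometryError, TriangleMesh, VoxelVolume

from conftest import ring_sensors


class TestFitSphere:
    def test_exact_samples_recovered(self):
        rng = np.random.default_rng(0)
        u = rng.normal(size=(200, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        centre, radius, resid = fit_sphere(u * 57.0 + (10.0, -4.0, 2.0))
        assert np.abs(centre - (10.0, -4.0, 2.0)).max() < 1e-9
        assert abs(radius - 57.0) < 1e-9 and resid < 1e-9

    def test_noisy_hemisphere_radius_within_1mm(self):
        rng = np.random.default_rng(1)
        u = rng.normal(size=(2000, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        u = u[u[:, 2] > 0]
        pts = u * 80.0 + rng.normal(0, 0.5, size=(len(u), 3))
        _, radius, _ = fit_sphere(pts)
        assert abs(radius - 80.0) < 1.0

    def test_residual_matches_brute_force(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(50, 3)) * 20
        centre, radius, resid = fit_sphere(pts)
        brute = np.sqrt(np.mean(
            (np.linalg.norm(pts - centre, axis=1) - radius) ** 2))
        assert np.isclose(resid, brute)

    def test_coplanar_raises(self):
        flat = np.c_[np.random.default_rng(3).uniform(size=(30, 2)) * 10,
                     np.zeros(30)]
        with pytest.raises(DegenerateGeometryError):
            fit_sphere(flat)


class TestSphereModel:
    def test_radial_dipole_silent(self, sphere_sensors):
        r0 = np.array([10.0, 20.0, 35.0])
        q = r0 / np.linalg.norm(r0) * 1e-8  # radial moment
        B = dipole_field_sphere(r0, q, sphere_sensors.positions,
                                sphere_sensors.orientations, np.zeros(3))
        assert np.abs(B).max() < 1e-25

    def test_central_dipole_silent(self, sphere_sensors):
        B = dipole_field_sphere(np.zeros(3), (1e-8, 0, 0),
                                sphere_sensors.positions,
                                sphere_sensors.orientations, np.zeros(3))
        assert np.abs(B).max() < 1e-25

    def test_matches_volume_current_oracle(self):
        """Sarvas closed form vs potential-solve + Geselowitz integral."""
        R = 0.08  # m
        ico = trimesh.creation.icosphere(subdivisions=4, radius=R)
        fc = np.array(ico.triangles_center)
        fn = np.array(ico.face_normals)
        fn[np.einsum("ij,ij->i", fn, fc) < 0] *= -1
        areas = np.array(ico.area_faces)
        r0 = np.array([0.0, 0.02, 0.045])
        q = np.array([1e-8, 0.0, 0.0])
        sigma = 0.33

        def phi_inf(pts):
            d = pts - r0
            dist = np.linalg.norm(d, axis=1)
            return (d @ q) / (4 * np.pi * sigma * dist ** 3)

        def grad_phi_inf(pts):
            d = pts - r0
            dist = np.linalg.norm(d, axis=1)[:, None]
            return (q[None, :] - 3 * d * (d @ q)[:, None] / dist ** 2) \
                / (4 * np.pi * sigma * dist ** 3)

        L = 25

        def basis(pts):
            r = np.linalg.norm(pts, axis=1)
            th = np.arccos(np.clip(pts[:, 2] / np.maximum(r, 1e-30), -1, 1))
            ph = np.arctan2(pts[:, 1], pts[:, 0])
            cols = []
            for l in range(1, L + 1):
                rad = (r / R) ** l
                for m in range(0, l + 1):
                    y = sph_harm_y(l, m, th, ph)
                    if m == 0:
                        cols.append(rad * y.real)
                    else:
                        f = np.sqrt(2) * (-1.0) ** m
                        cols.append(rad * f * y.real)
                        cols.append(rad * f * y.imag)
            return np.stack(cols, axis=1)

        def basis_grad(pts, h=1e-5):
            return np.stack([(basis(pts + e) - basis(pts - e)) / (2 * h)
                             for e in np.eye(3) * h], axis=1)

        # interior Neumann solve: total normal current vanishes on the shell
        D = np.einsum("fi,fik->fk", fn, basis_grad(fc))
        g = -np.einsum("fi,fi->f", fn, grad_phi_inf(fc))
        w = np.sqrt(areas)
        coef, *_ = np.linalg.lstsq(D * w[:, None], g * w, rcond=None)
        V = phi_inf(fc) + basis(fc) @ coef

        sensors = ring_sensors(15, radius=110.0, seed=5)
        pos_m = sensors.positions * 1e-3
        Bv = np.empty((len(pos_m), 3))
        for i, rr in enumerate(pos_m):
            d = rr - fc
            dist = np.linalg.norm(d, axis=1)
            integ = np.cross(fn, d) / dist[:, None] ** 3 * (V * areas)[:, None]
            Bv[i] = -(fw.MU0 * sigma / (4 * np.pi)) * integ.sum(axis=0)
        oracle = np.einsum("ij,ij->i", fw._primary_field(r0, q, pos_m) + Bv,
                           sensors.orientations)

        ours = dipole_field_sphere(r0 * 1e3, q, sensors.positions,
                                   sensors.orientations, np.zeros(3))
        assert np.linalg.norm(ours - oracle) / np.linalg.norm(ours) < 0.01

    def test_sensor_at_dipole_raises(self):
        with pytest.raises(ValueError):
            dipole_field_sphere((0, 0, 50.0), (1e-8, 0, 0),
                                np.array([[0, 0, 50.0]]),
                                np.array([[1.0, 0, 0]]), np.zeros(3))


class TestSingleShell:
    def test_agrees_with_sphere_within_2pc(self, shell_mesh, sphere_sensors):
        cond = ConductorModel.single_shell(shell_mesh, order=10)
        model = SingleShellModel(cond)
        r0 = np.array([30.0, 10.0, 40.0])
        q = np.array([0.0, 1e-8, 0.0])
        q -= r0 * (q @ r0) / (r0 @ r0)  # tangential
        Bs = model.field(r0, q, sphere_sensors)
        Ba = dipole_field_sphere(r0, q, sphere_sensors.positions,
                                 sphere_sensors.orientations, np.zeros(3))
        assert np.linalg.norm(Bs - Ba) / np.linalg.norm(Ba) < 0.02

    def test_radial_dipole_nearly_silent(self, shell_mesh, sphere_sensors):
        model = SingleShellModel(ConductorModel.single_shell(shell_mesh, 10))
        r0 = np.array([30.0, 10.0, 40.0])
        qr = r0 / np.linalg.norm(r0) * 1e-8
        qt = np.cross(r0, (0, 0, 1.0))
        qt *= 1e-8 / np.linalg.norm(qt)
        Br = model.field(r0, qr, sphere_sensors)
        Bt = model.field(r0, qt, sphere_sensors)
        assert np.linalg.norm(Br) < 0.01 * np.linalg.norm(Bt)

    def test_boundary_residual_decreases_with_order(self, shell_mesh):
        r0 = np.array([30.0, 10.0, 40.0])
        q = np.array([0.0, 1e-8, 0.0])
        resid = [SingleShellModel(ConductorModel.single_shell(shell_mesh, L)
                                  ).boundary_residual(r0, q)
                 for L in (4, 6, 8, 10)]
        assert all(b < a for a, b in zip(resid, resid[1:]))

    def test_source_outside_raises(self, shell_mesh, sphere_sensors):
        model = SingleShellModel(ConductorModel.single_shell(shell_mesh, 6))
        with pytest.raises(ValueError):
            model.field(np.array([0.0, 0.0, 120.0]), (1e-8, 0, 0),
                        sphere_sensors)

    def test_open_mesh_rejected(self, shell_mesh):
        open_mesh = TriangleMesh(shell_mesh.vertices, shell_mesh.faces[:-10])
        with pytest.raises(ValueError):
            ConductorModel.single_shell(open_mesh)


class TestLeadField:
    def source_space(self):
        pts = np.array([[0, 0, 30.0], [10, 0, 40.0], [0, -20, 20.0]])
        return SourceSpace(pts, 4.0)

    def test_linearity_in_moment(self, sphere_conductor, sphere_sensors):
        lf = build_leadfield(self.source_space(), sphere_sensors,
                             sphere_conductor)
        q = np.array([1.0, -2.0, 0.5]) * 1e-8
        b1 = lf.gains[0] @ q
        b2 = lf.gains[0] @ (2 * q)
        assert np.allclose(b2, 2 * b1, rtol=1e-12)

    def test_matches_direct_per_channel_calls(self, sphere_conductor,
                                              sphere_sensors):
        src = SourceSpace(np.array([[10.0, 0.0, 40.0]]), 4.0)
        lf = build_leadfield(src, sphere_sensors, sphere_conductor)
        for ax, e in enumerate(np.eye(3)):
            direct = dipole_field_sphere(src.points[0], e,
                                         sphere_sensors.positions,
                                         sphere_sensors.orientations,
                                         sphere_conductor.centre)
            assert np.allclose(lf.gains[0, :, ax], direct, rtol=1e-10)

    def test_field_magnitude_decreases_with_depth(self, sphere_conductor,
                                                  sphere_sensors):
        depths = np.linspace(0.85, 0.1, 8)
        norms = []
        for d in depths:
            src = SourceSpace(np.array([[0.0, 80.0 * d * 0.99, 0.0]]), 4.0)
            lf = build_leadfield(src, sphere_sensors, sphere_conductor)
            norms.append(np.linalg.norm(lf.gains[0] @ (1e-8, 0, 0)))
        assert all(b < a for a, b in zip(norms, norms[1:]))

    def test_source_outside_names_index(self, sphere_conductor, sphere_sensors):
        src = SourceSpace(np.array([[0, 0, 30.0], [0, 0, 100.0]]), 4.0)
        with pytest.raises(ValueError, match="source 1"):
            build_leadfield(src, sphere_sensors, sphere_conductor)

    def test_superposition_across_sources(self, sphere_conductor,
                                          sphere_sensors):
        lf = build_leadfield(self.source_space(), sphere_sensors,
                             sphere_conductor)
        q = np.array([1e-8, 2e-8, -1e-8])
        total = sum(lf.gains[i] @ q for i in range(3))
        stacked = np.einsum("scm,m->c", lf.gains, q)
        assert np.allclose(total, stacked, rtol=1e-12)

    def test_rotational_equivariance(self, sphere_conductor):
        from pseudomri.registration import params_to_matrix
        Rm = params_to_matrix(np.r_[np.zeros(3), np.deg2rad([20, -30, 45]),
                                    np.zeros(6)], np.zeros(3))[:3, :3]
        sens = ring_sensors(12, seed=9)
        r0 = np.array([15.0, -10.0, 35.0])
        q = np.array([1e-8, 0.5e-8, 0.0])
        B1 = dipole_field_sphere(r0, q, sens.positions, sens.orientations,
                                 np.zeros(3))
        B2 = dipole_field_sphere(Rm @ r0, Rm @ q, sens.positions @ Rm.T,
                                 sens.orientations @ Rm.T, np.zeros(3))
        assert np.abs(B1 - B2).max() < 1e-9 * np.abs(B1).max()

    def test_triaxial_completeness(self, sphere_conductor, sphere_sensors):
        """The three channels of one sensor reconstruct the field vector."""
        src = SourceSpace(np.array([[10.0, 0.0, 40.0]]), 4.0)
        lf = build_leadfield(src, sphere_sensors, sphere_conductor)
        q = np.array([1e-8, -2e-8, 0.5e-8])
        proj = lf.gains[0] @ q  # per channel
        sid = sphere_sensors.sensor_ids
        tri = sid == sid[0]
        triad = sphere_sensors.orientations[tri]
        recon = triad.T @ proj[tri]
        full = fw._sarvas_field(src.points[0] * 1e-3, q,
                                sphere_sensors.positions[tri][:1] * 1e-3)[0]
        assert np.allclose(recon, full, rtol=1e-12)

    def test_hdf5_roundtrip(self, tmp_path, sphere_conductor, sphere_sensors):
        lf = build_leadfield(self.source_space(), sphere_sensors,
                             sphere_conductor)
        lf.save(tmp_path / "lf.h5")
        back = LeadField.load(tmp_path / "lf.h5")
        assert np.allclose(back.gains, lf.gains)
        assert back.channel_labels == lf.channel_labels
        assert np.allclose(back.source_space.points, lf.source_space.points)


class TestSourceSpace:
    def test_from_mask_points_inside(self, small_phantom):
        src = SourceSpace.from_mask(small_phantom.brain_mask, 6.0)
        vox = np.round(small_phantom.brain_mask.world_to_voxel(src.points)
                       ).astype(int)
        vals = np.asarray(small_phantom.brain_mask.data)[tuple(vox.T)]
        assert (vals > 0).all()
        assert len(src) > 100
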