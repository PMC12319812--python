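"""LCMV machinery: covariance, regularisation, orientation optimisation,
weights, pseudo-T images and virtual electrodes."""

import numpy as np
import pytest

from pseudomri import beamformer as bf, synthetic as syn
from pseudomri.beamformer import CovarianceMatrix
from pseudomri.forward import SourceSpace, build_leadfield
from pseudomri.preprocess import TrialSet
from pseudomri.twin import _preprocess, _sphere_conductor, _surface_point

FS = 600.0


def make_trialset(data, fs=FS, conditions=None):
    n_tr, _, n_s = data.shape
    conditions = conditions or ["index"] * n_tr
    return TrialSet(data, np.arange(n_s) / fs, conditions, fs)


@pytest.fixture(scope="module")
def erd_setup():
    """Phantom with one planted ERD source, preprocessed trials and a
    lead field; reused by localisation / VE tests."""
    gt = syn.make_phantom_anatomy(64, 3.0, 78, seed=3)
    sens = syn.place_opm_array(gt.scalp, 32, 6.5, 0)
    cond = _sphere_conductor(gt.brain_mask)
    loc = _surface_point(gt.brain_mask, (-0.55, 0.05, 0.80), 0.7)
    tang = np.cross(loc - cond.centre, (0.0, 1.0, 0.0))
    tang /= np.linalg.norm(tang)
    gt.sources.append(syn.PlantedSource(loc, tang, 30e-9, 0.5, ("index",)))
    paradigm = syn.make_paradigm(10)
    rec, truth = syn.simulate_recording(gt, sens, cond, paradigm, FS,
                                        None, 5.0, 1e-12, seed=21)
    ts_broad, ts_beta = _preprocess(rec, sens)
    src = SourceSpace.from_mask(gt.brain_mask, 4.0)
    r = np.linalg.norm(src.points - cond.centre, axis=1)
    src = SourceSpace(src.points[r < 0.97 * cond.radius], 4.0)
    lf = build_leadfield(src, sens, cond)
    return dict(gt=gt, sens=sens, cond=cond, loc=loc, ori=tang, lf=lf,
                ts_broad=ts_broad, ts_beta=ts_beta, truth=truth)


class TestCovariance:
    def test_white_channels_near_identity(self):
        rng = np.random.default_rng(0)
        ts = make_trialset(rng.normal(size=(20, 6, 2000)))
        C = bf.compute_covariance(ts).matrix
        off = C - np.diag(np.diag(C))
        assert np.abs(np.diag(C) - 1.0).max() < 0.05
        assert np.abs(off).max() < 0.05

    def test_shared_signal_rank_one(self):
        t = np.sin(np.arange(500) * 0.1)
        data = np.stack([np.stack([t, 2 * t])] * 3)
        C = bf.compute_covariance(make_trialset(data)).matrix
        w = np.linalg.eigvalsh(C)
        assert w[-2] < 0.01 * w[-1]

    def test_matches_direct_formula_on_tiny_input(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(1, 3, 10))
        C = bf.compute_covariance(make_trialset(x)).matrix
        xc = x[0] - x[0].mean(axis=1, keepdims=True)
        assert np.allclose(C, xc @ xc.T / 9)

    def test_condition_selection(self):
        rng = np.random.default_rng(2)
        data = rng.normal(size=(4, 2, 100))
        ts = make_trialset(data, conditions=["a", "b", "a", "b"])
        Ca = bf.compute_covariance(ts, conditions="a")
        assert Ca.n_samples == 200

    def test_empty_selection_raises(self):
        ts = make_trialset(np.zeros((2, 2, 50)))
        with pytest.raises(ValueError):
            bf.compute_covariance(ts, conditions="nope")


class TestTikhonov:
    def test_forced_by_definition(self):
        C = CovarianceMatrix(np.diag([4.0, 1.0]))
        out = bf.regularize_tikhonov(C, 0.05)
        assert np.allclose(out.matrix, np.diag([4.2, 1.2]))
        assert np.isclose(out.regularisation, 0.2)

    def test_zero_fraction_unchanged(self):
        C = CovarianceMatrix(np.diag([4.0, 1.0]))
        assert np.allclose(bf.regularize_tikhonov(C, 0.0).matrix, C.matrix)

    def test_condition_number_decreases(self):
        rng = np.random.default_rng(3)
        A = rng.normal(size=(6, 6))
        C = CovarianceMatrix(A @ A.T)
        out = bf.regularize_tikhonov(C, 0.05)
        assert np.linalg.cond(out.matrix) < np.linalg.cond(C.matrix)


def pseudo_z(l, Cinv):
    """Noise-normalised output power of the unit-gain filter for forward
    vector l — the quantity the orientation optimiser maximises."""
    return (l @ Cinv @ l) / (l @ Cinv @ Cinv @ l)


class TestOptimalOrientation:
    def covariance(self, n=9, seed=4):
        rng = np.random.default_rng(seed)
        A = rng.normal(size=(n, 2 * n))
        return np.linalg.inv(A @ A.T / (2 * n) + 0.1 * np.eye(n))

    def test_white_covariance_gives_dominant_singular_direction(self):
        rng = np.random.default_rng(5)
        L = rng.normal(size=(9, 3)) * (3.0, 1.0, 0.3)
        eta = bf.optimal_orientation(L, np.eye(9))
        _, _, Vt = np.linalg.svd(L)
        assert min(np.linalg.norm(eta - Vt[0]), np.linalg.norm(eta + Vt[0])) < 1e-6

    def test_matches_dense_grid_search_within_2_degrees(self):
        rng = np.random.default_rng(6)
        L = rng.normal(size=(9, 3))
        Cinv = self.covariance()
        eta = bf.optimal_orientation(L, Cinv)
        # 1-degree Fibonacci grid over the half-sphere
        n = 41253 // 2
        i = np.arange(n)
        z = 1 - i / (n - 1)
        phi = i * np.pi * (3 - np.sqrt(5))
        s = np.sqrt(np.clip(1 - z ** 2, 0, None))
        grid = np.c_[s * np.cos(phi), s * np.sin(phi), z]
        powers = np.array([pseudo_z(L @ g, Cinv) for g in grid])
        best = grid[np.argmax(powers)]
        ang = np.degrees(np.arccos(np.clip(abs(best @ eta), -1, 1)))
        assert ang < 2.0

    def test_beats_10000_random_orientations(self):
        rng = np.random.default_rng(7)
        L = rng.normal(size=(9, 3))
        Cinv = self.covariance(seed=8)
        eta = bf.optimal_orientation(L, Cinv)
        ours = pseudo_z(L @ eta, Cinv)
        dirs = rng.normal(size=(10000, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        rand_best = max(pseudo_z(L @ d, Cinv) for d in dirs)
        assert ours >= rand_best - 1e-9 * abs(ours)

    def test_recovers_simulated_dipole_orientation(self, erd_setup):
        s = erd_setup
        C = bf.regularize_tikhonov(bf.compute_covariance(s["ts_beta"], None,
                                                         "index"))
        idx = s["lf"].source_space.nearest(s["loc"])
        eta = bf.optimal_orientation(s["lf"].gains[idx], C.inv)
        ang = np.degrees(np.arccos(np.clip(abs(eta @ s["ori"]), -1, 1)))
        assert ang < 5.0


class TestWeights:
    def test_identity_covariance_unit_vector(self):
        w = bf.lcmv_weights(np.array([1.0, 0, 0, 0]), np.eye(4))
        assert np.allclose(w, (1, 0, 0, 0))

    def test_unit_gain_always(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            A = rng.normal(size=(6, 12))
            Cinv = np.linalg.inv(A @ A.T / 12 + 0.05 * np.eye(6))
            l = rng.normal(size=6)
            w = bf.lcmv_weights(l, Cinv)
            assert abs(w @ l - 1.0) < 1e-10

    def test_minimum_variance_vs_random_unit_gain(self):
        rng = np.random.default_rng(10)
        A = rng.normal(size=(8, 30))
        C = A @ A.T / 30 + 0.05 * np.eye(8)
        Cinv = np.linalg.inv(C)
        l = rng.normal(size=8)
        w = bf.lcmv_weights(l, Cinv)
        ours = w @ C @ w
        for _ in range(1000):
            v = rng.normal(size=8)
            v = v - w * 0  # arbitrary direction, then enforce unit gain
            if abs(v @ l) < 1e-9:
                continue
            v = v / (v @ l)
            assert ours <= v @ C @ v + 1e-12


class TestPseudoT:
    def test_stationary_data_flat_map(self, erd_setup):
        rng = np.random.default_rng(11)
        s = erd_setup
        n_ch = s["sens"].n_channels
        data = rng.normal(size=(16, n_ch, int(3.5 * FS)))
        ts = make_trialset(data)
        C = bf.regularize_tikhonov(bf.compute_covariance(ts))
        tmap = bf.pseudo_t_map(s["lf"], ts, (0.3, 0.8), (2.5, 3.0), C)
        assert np.abs(tmap.values).max() < 0.05

    def test_bounded_by_construction(self, erd_setup):
        s = erd_setup
        C = bf.regularize_tikhonov(bf.compute_covariance(s["ts_beta"], None,
                                                         "index"))
        tmap = bf.pseudo_t_map(s["lf"], s["ts_beta"], (0.3, 0.8), (2.5, 3.0),
                               C, "index")
        assert tmap.values.min() >= -1.0 and tmap.values.max() <= 1.0

    def test_erd_source_localised_within_one_spacing(self, erd_setup):
        s = erd_setup
        C = bf.regularize_tikhonov(bf.compute_covariance(s["ts_beta"], None,
                                                         "index"))
        tmap = bf.pseudo_t_map(s["lf"], s["ts_beta"], (0.3, 0.8), (2.5, 3.0),
                               C, "index")
        err = np.linalg.norm(tmap.peak_location - s["loc"])
        assert err <= 2 * s["lf"].source_space.spacing
        assert tmap.values[tmap.peak_index] < -0.1  # a clear power decrease


class TestVirtualElectrode:
    def test_noiseless_source_reconstructed(self):
        gt = syn.make_phantom_anatomy(64, 3.0, 78, seed=3)
        sens = syn.place_opm_array(gt.scalp, 32, 6.5, 0)
        cond = _sphere_conductor(gt.brain_mask)
        loc = _surface_point(gt.brain_mask, (-0.5, 0.0, 0.8), 0.6)
        tang = np.cross(loc - cond.centre, (0.0, 1.0, 0.0))
        tang /= np.linalg.norm(tang)
        gt.sources.append(syn.PlantedSource(loc, tang, 30e-9, 0.0))
        paradigm = syn.make_paradigm(4)
        rec, truth = syn.simulate_recording(
            gt, sens, cond, paradigm, FS, noise_sd=1e-18, snr=None,
            n_background=0, seed=31)
        ts = bf.compute_covariance  # noqa: F841 (keep import visible)
        from pseudomri.preprocess import epoch
        trials = epoch(rec, (0.0, 3.5))
        src = SourceSpace(np.atleast_2d(loc), 4.0)
        lf = build_leadfield(src, sens, cond)
        C = bf.regularize_tikhonov(bf.compute_covariance(trials))
        ve = bf.virtual_electrode(loc, lf, trials, C)
        true_tc = truth["timecourses"][0][:trials.data.shape[2]]
        r = np.corrcoef(ve[0], true_tc)[0, 1]
        assert abs(r) > 0.99

    def test_linearity(self, erd_setup):
        s = erd_setup
        C = bf.regularize_tikhonov(bf.compute_covariance(s["ts_broad"]))
        ve1 = bf.virtual_electrode(s["loc"], s["lf"], s["ts_broad"], C)
        doubled = TrialSet(2 * s["ts_broad"].data, s["ts_broad"].times,
                           s["ts_broad"].conditions, FS,
                           s["ts_broad"].retained.copy())
        ve2 = bf.virtual_electrode(s["loc"], s["lf"], doubled, C)
        assert np.allclose(ve2, 2 * ve1, rtol=1e-10)

    def test_location_outside_space_raises(self, erd_setup):
        s = erd_setup
        C = bf.regularize_tikhonov(bf.compute_covariance(s["ts_broad"]))
        with pytest.raises(ValueError):
            bf.virtual_electrode((0.0, 0.0, 500.0), s["lf"], s["ts_broad"], C)
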