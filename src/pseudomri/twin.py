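"""Phantom "twin" experiments: the same simulated recording analysed
with the true anatomy and with a pseudo-MRI built from a noisy head
scan.

This is the digital counterpart of validating the pseudo-MRI approach
against individual anatomy: one phantom subject provides ground-truth
anatomy, sensors and a recording; the pseudo pipeline only ever sees
the template anatomy and the simulated structured-light scan. Both
pipelines then run identical beamformer analyses and the module
reports the discrepancy metrics (medoid distances, beta-peak
separation, pseudo-T map / TFS / connectome correlations).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

from . import beamformer as bf
from . import connectivity as conn
from . import preprocess as pre
from . import registration as reg
from . import synthetic as syn
from . import warp
from .forward import ConductorModel, SourceSpace, build_leadfield, fit_sphere
from .geometry import PointCloud, VoxelVolume, extract_outer_surface
from .registration import AffineTransform, RigidTransform, compose, invert
from .sensors import SensorArray


def random_rigid(rng: np.random.Generator, max_rotation_deg: float,
                 max_translation_mm: float, centre=None) -> RigidTransform:
    p = np.zeros(12)
    p[0:3] = rng.uniform(-max_translation_mm, max_translation_mm, 3)
    p[3:6] = np.deg2rad(rng.uniform(-max_rotation_deg, max_rotation_deg, 3))
    c = np.zeros(3) if centre is None else np.asarray(centre, float)
    return RigidTransform(reg.params_to_matrix(p, c))


def random_affine(rng: np.random.Generator, max_rotation_deg: float,
                  max_translation_mm: float, scale_range=(0.9, 1.1),
                  max_shear: float = 0.05, centre=None) -> AffineTransform:
    p = np.zeros(12)
    p[0:3] = rng.uniform(-max_translation_mm, max_translation_mm, 3)
    p[3:6] = np.deg2rad(rng.uniform(-max_rotation_deg, max_rotation_deg, 3))
    p[6:9] = np.log(rng.uniform(*scale_range, 3))
    p[9:12] = rng.uniform(-max_shear, max_shear, 3)
    c = np.zeros(3) if centre is None else np.asarray(centre, float)
    return AffineTransform(reg.params_to_matrix(p, c))


@dataclass
class TwinConfig:
    """Problem sizes and study conditions for the twin experiment."""

    anatomy_size: int = 80
    voxel_mm: float = 2.4
    n_regions: int = 78
    n_sensors: int = 32
    standoff_mm: float = 6.5
    scan_noise_sd: float = 0.5  # structured-light point noise (mm)
    scan_points: int = 8000
    scan_rot_deg: float = 8.0  # scanner-frame misalignment to recover
    scan_trans_mm: float = 25.0
    n_per_condition: int = 12
    fs: float = 600.0
    snr: float = 5.0
    erd_depth: float = 0.5
    source_amp: float = 30e-9
    grid_mm: float = 6.0
    interference_amplitude: float = 1e-12  # tesla (homogeneous drift)
    network_rho: float = 0.6
    n_network_pairs: int = 3
    network_amp: float = 20e-9
    isolate_coregistration: bool = False
    template_seed: int = 999


def make_template(config: TwinConfig) -> syn.PhantomGroundTruth:
    return syn.make_phantom_anatomy(config.anatomy_size, config.voxel_mm,
                                    config.n_regions, config.template_seed)


# ---------------------------------------------------------------------------
# subject construction
# ---------------------------------------------------------------------------


def _surface_point(brain_mask: VoxelVolume, direction, depth: float = 0.8):
    """Point at a fractional depth along a ray from the brain centroid."""
    on = np.argwhere(np.asarray(brain_mask.data) > 0)
    pts = brain_mask.voxel_to_world(on)
    c = pts.mean(axis=0)
    u = np.asarray(direction, float)
    u = u / np.linalg.norm(u)
    t = (pts - c) @ u
    return c + u * depth * t.max()


def _plant_sources(subject: syn.PhantomGroundTruth, config: TwinConfig,
                   medoids, conductor: ConductorModel) -> None:
    """Two task (ERD) sources plus an envelope-correlated network."""
    inside = np.linalg.norm(medoids[["x", "y", "z"]].to_numpy(float)
                            - conductor.centre, axis=1) < 0.93 * conductor.radius
    medoids = medoids[inside]
    for cond, direction in (("index", (-0.55, 0.05, 0.80)),
                            ("little", (-0.60, -0.10, 0.78))):
        loc = _surface_point(subject.brain_mask, direction, depth=0.75)
        radial = loc - subject.brain_mask.voxel_to_world(
            (np.asarray(subject.brain_mask.shape) - 1) / 2)[0]
        tang = np.cross(radial, (0.0, 1.0, 0.0))
        tang /= np.linalg.norm(tang)
        subject.sources.append(syn.PlantedSource(
            loc, tang, config.source_amp, config.erd_depth, (cond,)))
    rng = np.random.default_rng(subject.seed + 17)
    ids = medoids.index.to_numpy()
    picks = rng.choice(ids, size=2 * config.n_network_pairs, replace=False)
    for pair in range(config.n_network_pairs):
        for rid in picks[2 * pair:2 * pair + 2]:
            loc = medoids.loc[rid, ["x", "y", "z"]].to_numpy(float)
            ori = rng.normal(size=3)
            radial = loc - medoids[["x", "y", "z"]].mean().to_numpy()
            ori -= radial * (ori @ radial) / (radial @ radial)
            ori /= np.linalg.norm(ori)
            subject.sources.append(syn.PlantedSource(
                loc, ori, config.network_amp, 0.0, (),
                envelope_rho=config.network_rho, envelope_group=pair))


@dataclass
class TwinSubject:
    subject: syn.PhantomGroundTruth
    sensors: SensorArray
    scan: PointCloud
    pseudo: warp.PseudoMRIResult
    template_to_sensor: AffineTransform
    coreg_error_ind: RigidTransform
    planted_pairs: list = field(default_factory=list)


def build_twin_subject(seed: int, template: syn.PhantomGroundTruth,
                       config: TwinConfig) -> TwinSubject:
    """Phantom subject, its scan, and the fitted pseudo-MRI."""
    rng = np.random.default_rng(seed)
    subject = syn.make_phantom_anatomy(config.anatomy_size, config.voxel_mm,
                                       config.n_regions, seed)
    sensors = syn.place_opm_array(subject.scalp, config.n_sensors,
                                  config.standoff_mm, seed)
    centre = subject.scalp.vertices.mean(axis=0)

    # scan of the bare head in an arbitrary scanner frame
    D = random_rigid(rng, config.scan_rot_deg, config.scan_trans_mm, centre)
    zmin, zmax = subject.scalp.vertices[:, 2].min(), subject.scalp.vertices[:, 2].max()
    plane_pt = D.apply(np.array([centre[0], centre[1],
                                 zmin + 0.10 * (zmax - zmin)]))[0]
    plane_n = D.apply_vectors(np.array([0.0, 0.0, 1.0]))[0]
    scan = syn.simulate_headscan(subject.scalp, D, config.scan_noise_sd,
                                 (plane_pt, plane_n), 0.0, config.scan_points,
                                 seed + 1)

    pseudo = warp.generate_pseudo_mri(
        template.anatomy, scan,
        syn.approximate_fiducials(scan.points),
        syn.approximate_fiducials(template.scalp.vertices))

    # optical coregistration: scan -> anatomy (sensor) frame, estimated
    icp = reg.icp_refine(scan, subject.scalp,
                         init=reg.fit_rigid_landmarks(
                             syn.approximate_fiducials(scan.points),
                             syn.approximate_fiducials(subject.scalp.vertices)),
                         max_iter=400, tol=1e-7)
    template_to_sensor = compose(icp.transform, pseudo.transform)

    # independent optical coregistration for the individual-MRI pipeline
    D2 = random_rigid(rng, config.scan_rot_deg, config.scan_trans_mm, centre)
    scan2 = syn.simulate_headscan(subject.scalp, D2, config.scan_noise_sd,
                                  (D2.apply(np.array([centre[0], centre[1],
                                                      zmin + 0.10 * (zmax - zmin)]))[0],
                                   D2.apply_vectors(np.array([0.0, 0.0, 1.0]))[0]),
                                  0.0, config.scan_points, seed + 2)
    icp2 = reg.icp_refine(scan2, subject.scalp,
                          init=reg.fit_rigid_landmarks(
                              syn.approximate_fiducials(scan2.points),
                              syn.approximate_fiducials(subject.scalp.vertices)),
                          max_iter=400, tol=1e-7)
    # residual rigid error of the individual pipeline's coregistration
    coreg_error_ind = RigidTransform(
        reg._reorthogonalise((compose(icp2.transform, D2)).matrix))

    return TwinSubject(subject, sensors, scan, pseudo, template_to_sensor,
                       coreg_error_ind)


# ---------------------------------------------------------------------------
# per-pipeline analysis
# ---------------------------------------------------------------------------


def _extracted_brain(gt: syn.PhantomGroundTruth) -> VoxelVolume:
    """Grey-level anatomy masked to the brain (skull-stripped image)."""
    return VoxelVolume(np.asarray(gt.anatomy.data, float)
                       * (np.asarray(gt.brain_mask.data) > 0),
                       gt.anatomy.affine.copy())


def _sphere_conductor(brain_mask: VoxelVolume) -> ConductorModel:
    surf = extract_outer_surface(brain_mask, 0.5)
    centre, radius, _ = fit_sphere(surf.vertices)
    return ConductorModel.sphere(centre, radius)


def _preprocess(rec: pre.Recording, sensors: SensorArray):
    nyq = rec.rate / 2
    notches = [f for f in (50.0, 100.0, 150.0) if f < nyq * 0.98]
    rec = pre.notch_filter(rec, notches)
    rec = pre.bandpass(rec, 1.0, min(150.0, nyq * 0.95))
    rec = pre.homogeneous_field_correction(rec, sensors)
    rec_beta = pre.bandpass(rec, 13.0, 30.0)
    ts_broad = pre.epoch(rec, (0.0, 3.5))
    ts_broad = pre.reject_variance_outliers(ts_broad, 3.0)
    ts_beta = pre.epoch(rec_beta, (0.0, 3.5))
    ts_beta.retained = ts_broad.retained.copy()
    return ts_broad, ts_beta


def analyse_pipeline(brain_mask: VoxelVolume, parc: warp.Parcellation,
                     sensors: SensorArray, ts_broad, ts_beta,
                     config: TwinConfig, condition: str = "index") -> dict:
    """Beamformer analyses for one anatomy (true or pseudo)."""
    conductor = _sphere_conductor(brain_mask)
    src = SourceSpace.from_mask(brain_mask, config.grid_mm)
    # the sphere approximates the ellipsoidal brain: keep grid points
    # safely inside the conductor
    r = np.linalg.norm(src.points - conductor.centre, axis=1)
    src = SourceSpace(src.points[r < 0.97 * conductor.radius], src.spacing)
    lf = build_leadfield(src, sensors, conductor)

    C = bf.regularize_tikhonov(bf.compute_covariance(ts_beta, None, condition))
    tmap = bf.pseudo_t_map(lf, ts_beta, (0.3, 0.8), (2.5, 3.0), C, condition)

    Cb = bf.regularize_tikhonov(bf.compute_covariance(ts_broad, None, condition))
    ve = bf.virtual_electrode(tmap.peak_location, lf, ts_broad, Cb, condition)
    tfs = conn.trial_tfs(ve, ts_broad.rate, ts_broad.times, (2.5, 3.0))

    medoids = warp.region_medoids(parc)
    Call = bf.regularize_tikhonov(bf.compute_covariance(ts_beta))
    regional = regional_signals(lf, medoids, ts_beta, Call)
    connectome = conn.aec_connectome(regional, ts_beta.rate,
                                     medoids.index.to_numpy())
    return {"conductor": conductor, "source_space": src, "tmap": tmap,
            "peak": tmap.peak_location, "tfs": tfs, "medoids": medoids,
            "connectome": connectome,
            "global_connectivity": conn.global_connectivity(connectome)}


def regional_signals(lf, medoids, ts_beta, C, window=(0.1, 3.4)) -> np.ndarray:
    """Beamformed time course at each region medoid, trials cropped to
    the analysis window and concatenated (regions x samples)."""
    sl = ts_beta.window_slice(*window)
    keep = ts_beta.select()
    data = ts_beta.data[keep][:, :, sl]
    flat = np.concatenate(list(data), axis=1)
    rows = []
    for rid in medoids.index:
        loc = medoids.loc[rid, ["x", "y", "z"]].to_numpy(float)
        idx = lf.source_space.nearest(loc)
        eta = bf.optimal_orientation(lf.gains[idx], C.inv)
        w = bf.lcmv_weights(lf.gains[idx] @ eta, C.inv)
        rows.append((w / np.linalg.norm(w)) @ flat)
    return np.array(rows)


def map_image_correlation(a, b) -> float:
    """Pearson r between two pseudo-T images on different grids, via
    nearest-point pairing within one grid spacing."""
    tree = cKDTree(b.source_space.points)
    d, j = tree.query(a.source_space.points)
    ok = d <= max(a.source_space.spacing, b.source_space.spacing)
    if ok.sum() < 10:
        return float("nan")
    return float(np.corrcoef(a.values[ok], b.values[j[ok]])[0, 1])


# ---------------------------------------------------------------------------
# full subject run and study aggregation
# ---------------------------------------------------------------------------


def run_twin_subject(seed: int, template: syn.PhantomGroundTruth | None = None,
                     config: TwinConfig | None = None) -> dict:
    """Simulate one phantom subject and compare the true-anatomy and
    pseudo-MRI analysis pipelines on the same recording."""
    config = config or TwinConfig()
    template = template if template is not None else make_template(config)
    tw = build_twin_subject(seed, template, config)
    subject, sensors = tw.subject, tw.sensors

    # region definitions: atlas registered to each anatomy; the
    # individual side registers the extracted grey-level brains (internal
    # contrast pins down orientation far better than a binary mask)
    greylevel = reg.RegistrationConfig(dof=12, bins=32, boundary_band_vox=2,
                                       domain="support")
    parc_ind = warp.map_parcellation(template.parcellation,
                                     _extracted_brain(template),
                                     _extracted_brain(subject), greylevel)
    pseudo_brain = reg.resample(template.brain_mask, tw.template_to_sensor,
                                subject.brain_mask, mode="nearest")
    parc_ps = warp.Parcellation(
        reg.resample(template.parcellation.labels, tw.template_to_sensor,
                     subject.brain_mask, mode="nearest"),
        template.parcellation.table.copy())

    # individual pipeline carries its own (estimated) coregistration error
    E = tw.coreg_error_ind
    if config.isolate_coregistration:
        iso = warp.isolate_coregistration_error(
            reg.resample(_extracted_brain(subject), E, subject.brain_mask,
                         "trilinear"),
            reg.resample(_extracted_brain(template), tw.template_to_sensor,
                         subject.brain_mask, "trilinear"),
            reg.RegistrationConfig(dof=6, bins=32, boundary_band_vox=2,
                                   domain="support"))
        E = RigidTransform(reg._reorthogonalise((compose(iso, E)).matrix))
    ind_brain = reg.resample(subject.brain_mask, E, subject.brain_mask, "nearest")
    parc_ind = warp.Parcellation(
        reg.resample(parc_ind.labels, E, subject.brain_mask, "nearest"),
        parc_ind.table)

    # recording simulated from the *true* geometry
    med_true = warp.region_medoids(subject.parcellation)
    conductor_true = _sphere_conductor(subject.brain_mask)
    _plant_sources(subject, config, med_true, conductor_true)
    paradigm = syn.make_paradigm(config.n_per_condition)
    rec, truth = syn.simulate_recording(
        subject, sensors, conductor_true, paradigm, config.fs, None,
        config.snr, config.interference_amplitude, seed=seed + 3)
    ts_broad, ts_beta = _preprocess(rec, sensors)

    res_ind = analyse_pipeline(ind_brain, parc_ind, sensors, ts_broad,
                               ts_beta, config)
    res_ps = analyse_pipeline(pseudo_brain, parc_ps, sensors, ts_broad,
                              ts_beta, config)

    _, med_summary = warp.medoid_discrepancy(res_ind["medoids"],
                                             res_ps["medoids"])
    true_peak = np.asarray(subject.sources[0].location, float)
    return {
        "seed": seed,
        "medoid_median_mm": med_summary["median_mm"],
        "medoid_mad_mm": med_summary["mad_mm"],
        "peak_separation_mm": float(np.linalg.norm(res_ind["peak"]
                                                   - res_ps["peak"])),
        "peak_error_ind_mm": float(np.linalg.norm(res_ind["peak"] - true_peak)),
        "peak_error_ps_mm": float(np.linalg.norm(res_ps["peak"] - true_peak)),
        "tmap_correlation": map_image_correlation(res_ind["tmap"], res_ps["tmap"]),
        "tfs_correlation": float(np.corrcoef(
            res_ind["tfs"].values.ravel(), res_ps["tfs"].values.ravel())[0, 1]),
        "connectome_correlation": conn.compare_connectomes(
            res_ind["connectome"], res_ps["connectome"]),
        "global_connectivity_ind": res_ind["global_connectivity"],
        "global_connectivity_ps": res_ps["global_connectivity"],
        "ind": res_ind, "ps": res_ps,
    }


def run_twin_study(n_subjects: int = 5, seed: int = 1,
                   config: TwinConfig | None = None) -> dict:
    """Run several phantom subjects and aggregate the comparison."""
    config = config or TwinConfig()
    template = make_template(config)
    subjects = [run_twin_subject(seed + 101 * i, template, config)
                for i in range(n_subjects)]
    gci = np.array([s["global_connectivity_ind"] for s in subjects])
    gcp = np.array([s["global_connectivity_ps"] for s in subjects])
    out = {
        "subjects": subjects,
        "median_medoid_mm": float(np.median([s["medoid_median_mm"]
                                             for s in subjects])),
        "median_peak_separation_mm": float(np.median(
            [s["peak_separation_mm"] for s in subjects])),
        "median_tmap_correlation": float(np.median(
            [s["tmap_correlation"] for s in subjects])),
        "median_tfs_correlation": float(np.median(
            [s["tfs_correlation"] for s in subjects])),
        "median_connectome_correlation": float(np.median(
            [s["connectome_correlation"] for s in subjects])),
        "global_connectivity_correlation": float(
            np.corrcoef(gci, gcp)[0, 1]) if n_subjects >= 3 else float("nan"),
    }
    return out


# ---------------------------------------------------------------------------
# anatomy-only sweep (no MEG): medoid discrepancy vs scan noise
# ---------------------------------------------------------------------------


def medoid_discrepancy_for_subject(seed: int, template, config: TwinConfig,
                                   isolate: bool = False) -> float:
    cfg = replace(config, isolate_coregistration=isolate)
    tw = build_twin_subject(seed, template, cfg)
    subject = tw.subject
    greylevel = reg.RegistrationConfig(dof=12, bins=32, boundary_band_vox=2,
                                       domain="support")
    parc_ind = warp.map_parcellation(template.parcellation,
                                     _extracted_brain(template),
                                     _extracted_brain(subject), greylevel)
    parc_ps = warp.Parcellation(
        reg.resample(template.parcellation.labels, tw.template_to_sensor,
                     subject.brain_mask, mode="nearest"),
        template.parcellation.table.copy())
    E = tw.coreg_error_ind
    if isolate:
        iso = warp.isolate_coregistration_error(
            reg.resample(_extracted_brain(subject), E, subject.brain_mask,
                         "trilinear"),
            reg.resample(_extracted_brain(template), tw.template_to_sensor,
                         subject.brain_mask, "trilinear"),
            reg.RegistrationConfig(dof=6, bins=32, boundary_band_vox=2,
                                   domain="support"))
        E = RigidTransform(reg._reorthogonalise((compose(iso, E)).matrix))
    parc_ind = warp.Parcellation(
        reg.resample(parc_ind.labels, E, subject.brain_mask, "nearest"),
        parc_ind.table)
    _, summary = warp.medoid_discrepancy(warp.region_medoids(parc_ind),
                                         warp.region_medoids(parc_ps))
    return summary["median_mm"]


def medoid_noise_sweep(noise_levels, n_subjects: int = 5, seed: int = 1,
                       config: TwinConfig | None = None) -> list:
    """Median medoid discrepancy (across subjects) per scan-noise level."""
    config = config or TwinConfig()
    template = make_template(config)
    out = []
    for ns in noise_levels:
        cfg = replace(config, scan_noise_sd=ns)
        meds = [medoid_discrepancy_for_subject(seed + 101 * i, template, cfg)
                for i in range(n_subjects)]
        out.append(float(np.median(meds)))
    return out
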