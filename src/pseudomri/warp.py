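"""Pseudo-MRI generation and sensor coregistration.

The pseudo-MRI pipeline turns a template anatomical volume plus a 3D
head-surface scan into a subject-specific "pseudo-MRI": the template
scalp is extracted, the scan is rigidly aligned to it (landmarks + ICP),
both surfaces are cropped to common coverage and voxelised via convex
hulls, a 12-DOF affine warps the template head mask onto the subject
head mask, and the grey-level template is resampled through the
composed transform into the subject's frame.

Also here: chaining of the helmet -> scan -> anatomy sensor
coregistration, atlas-parcellation mapping, region medoids and their
discrepancy summary, and the rigid brain-to-brain alignment used to
isolate coregistration error from anatomy error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import geometry, registration
from .geometry import PointCloud, TriangleMesh, VoxelVolume
from .registration import (AffineTransform, RegistrationConfig, RigidTransform,
                           compose, invert, resample)
from .sensors import SensorArray


class PipelineStageError(RuntimeError):
    """An error in a named stage of a multi-stage pipeline."""

    def __init__(self, stage: str, err: Exception):
        super().__init__(f"stage '{stage}': {err}")
        self.stage = stage
        self.cause = err


@dataclass
class Parcellation:
    """Integer label volume plus a region table (id, name)."""

    labels: VoxelVolume
    table: pd.DataFrame

    def __post_init__(self):
        present = set(np.unique(np.asarray(self.labels.data)).astype(int)) - {0}
        known = set(self.table["id"].astype(int))
        if not present <= known:
            raise ValueError(f"labels {sorted(present - known)} missing from table")

    @property
    def region_ids(self) -> np.ndarray:
        return self.table["id"].to_numpy(int)


@dataclass
class PseudoMRIConfig:
    scalp_threshold: float | None = None  # default: half the robust max
    crop_fraction: float = 0.12  # axial crop plane height as a fraction of
    # the template scalp's z extent above its floor (inion-level default)
    registration: RegistrationConfig = field(default_factory=RegistrationConfig)
    icp_max_iter: int = 400
    icp_tol: float = 1e-7
    cap_offset: float = 0.0  # uniform scalp offset (mm) to absorb hair/cap
    coverage_margin: float = 8.0  # template kept only within this distance
    # (mm) of the scan, so both hulls describe the same head area


@dataclass
class PseudoMRIResult:
    pseudo: VoxelVolume
    transform: AffineTransform  # template world -> subject (scan) world
    rigid_scan_to_template: RigidTransform
    affine_cost: float
    scan_mask: VoxelVolume
    template_mask: VoxelVolume


def _stage(name):
    def deco(fn):
        def run(*a, **k):
            try:
                return fn(*a, **k)
            except Exception as err:  # noqa: BLE001 - tagged and re-raised
                raise PipelineStageError(name, err) from err
        return run
    return deco


def generate_pseudo_mri(template: VoxelVolume, headscan: PointCloud,
                        scan_landmarks: np.ndarray,
                        template_landmarks: np.ndarray,
                        config: PseudoMRIConfig | None = None) -> PseudoMRIResult:
    """Warp a template volume to a subject's head-surface scan.

    ``scan_landmarks`` / ``template_landmarks`` are corresponding
    fiducial-like points (>= 3, e.g. nasion/inion/preauriculars) seeding
    the rigid alignment that ICP then refines. Returns the pseudo-MRI in
    the scan's world frame and the full template -> subject transform.
    """
    config = config or PseudoMRIConfig()

    thr = config.scalp_threshold
    if thr is None:
        # low threshold above air/background: the head is one solid
        # supra-threshold component whose outer isosurface is the scalp
        data = np.asarray(template.data, float)
        thr = 0.15 * np.percentile(data[data > 0], 99)
    scalp_t = _stage("template-scalp")(geometry.extract_outer_surface)(template, thr)

    rigid0 = _stage("landmark-align")(registration.fit_rigid_landmarks)(
        scan_landmarks, template_landmarks)
    icp = _stage("icp-align")(registration.icp_refine)(
        headscan, scalp_t, init=rigid0,
        max_iter=config.icp_max_iter, tol=config.icp_tol)
    rigid = icp.transform  # scan world -> template world

    scan_t = rigid.apply(headscan.points)
    zmin, zmax = scalp_t.vertices[:, 2].min(), scalp_t.vertices[:, 2].max()
    plane_pt = np.array([0.0, 0.0, zmin + config.crop_fraction * (zmax - zmin)])
    normal = np.array([0.0, 0.0, 1.0])
    scan_crop = _stage("crop")(geometry.crop_below_plane)(
        PointCloud(scan_t), plane_pt, normal)
    # digitise the template scalp the same way the scan digitised the
    # subject (area-uniform samples, matched count) so both convex hulls
    # carry the same sampling bias ...
    tmpl_pts, _ = geometry.sample_surface_points(
        scalp_t, max(len(headscan), 2000), np.random.default_rng(0))
    scalp_crop = _stage("crop")(geometry.crop_below_plane)(
        PointCloud(tmpl_pts), plane_pt, normal)
    # ... and restrict the template to the area the scan actually covers
    # (a partially cropped scan must be compared like for like)
    from scipy.spatial import cKDTree
    d, _ = cKDTree(scan_crop.points).query(scalp_crop.points)
    covered = d <= config.coverage_margin
    if covered.sum() >= 100:
        scalp_crop = PointCloud(scalp_crop.points[covered])

    scan_mask = _stage("hull-scan")(geometry.fill_convex_hull)(scan_crop, template)
    tmpl_mask = _stage("hull-template")(geometry.fill_convex_hull)(
        scalp_crop, template)

    reg = _stage("affine")(registration.optimize_affine)(
        tmpl_mask, scan_mask, config.registration)
    total = compose(invert(rigid), reg.transform)  # template -> scan frame

    target = _axis_aligned_grid(total.apply(_volume_corners(template)),
                                template.voxel_sizes.mean())
    pseudo = _stage("resample")(resample)(template, total, target, "trilinear")
    return PseudoMRIResult(pseudo, total, rigid, reg.cost, scan_mask, tmpl_mask)


def _volume_corners(vol: VoxelVolume) -> np.ndarray:
    shape = np.asarray(vol.shape) - 1
    corners = np.array([[i, j, k] for i in (0, shape[0]) for j in (0, shape[1])
                        for k in (0, shape[2])], float)
    return vol.voxel_to_world(corners)


def _axis_aligned_grid(points: np.ndarray, spacing: float) -> VoxelVolume:
    lo = points.min(axis=0) - spacing
    hi = points.max(axis=0) + spacing
    shape = np.maximum(np.ceil((hi - lo) / spacing).astype(int) + 1, 1)
    aff = np.diag([spacing, spacing, spacing, 1.0])
    aff[:3, 3] = lo
    return VoxelVolume(np.zeros(shape, np.float32), aff)


# ---------------------------------------------------------------------------
# sensor coregistration chain
# ---------------------------------------------------------------------------


@dataclass
class CoregStage:
    """One rigid alignment in the sensor coregistration chain.

    ``src_cloud`` is refined onto ``dst_surface`` by ICP after a
    landmark seed (both landmark sets in their own frames).
    """

    name: str
    src_cloud: PointCloud
    dst_surface: object  # PointCloud | TriangleMesh
    src_landmarks: np.ndarray
    dst_landmarks: np.ndarray
    max_iter: int = 40
    tol: float = 1e-3


def chain_sensor_coregistration(sensors: SensorArray, stages) -> tuple:
    """Compose per-stage rigid alignments and map the sensor array.

    Stages are applied in order (helmet -> with-helmet scan ->
    without-helmet scan -> anatomy); positions map through the composed
    rigid transform, orientations through its rotation part. Returns
    ``(mapped_array, total_transform, stage_results)``.
    """
    total = RigidTransform.identity()
    results = []
    for st in stages:
        # each stage's inputs live in the previous stage's output frame,
        # so stages are aligned independently and composed afterwards
        try:
            seed = registration.fit_rigid_landmarks(st.src_landmarks,
                                                    st.dst_landmarks)
            icp = registration.icp_refine(st.src_cloud, st.dst_surface,
                                          init=seed, max_iter=st.max_iter,
                                          tol=st.tol)
        except Exception as err:  # noqa: BLE001
            raise PipelineStageError(st.name, err) from err
        results.append((st.name, icp))  # icp.converged flags non-convergence
        total = compose(icp.transform, total)
    return sensors.transformed(total), total, results


# ---------------------------------------------------------------------------
# parcellation mapping and medoids
# ---------------------------------------------------------------------------


def map_parcellation(atlas: Parcellation, atlas_brain: VoxelVolume,
                     subject_brain: VoxelVolume,
                     config: RegistrationConfig | None = None) -> Parcellation:
    """Carry an atlas parcellation into a subject's brain.

    Affinely registers the atlas brain mask to the subject brain mask
    (12 DOF, correlation ratio) and applies the same transform to the
    label volume with nearest-neighbour resampling onto the subject grid.
    """
    config = config or RegistrationConfig(dof=12)
    reg = registration.optimize_affine(atlas_brain, subject_brain, config)
    labels = resample(atlas.labels, reg.transform, subject_brain, mode="nearest")
    return Parcellation(labels, atlas.table.copy())


def region_medoids(parc: Parcellation) -> pd.DataFrame:
    """World-frame medoid of every region.

    The medoid is the member voxel centre minimising the summed
    Euclidean distance to all member centres (computed in mm); ties
    break to the lowest linear voxel index. Empty regions are recorded
    with NaN coordinates rather than raising.
    """
    data = np.asarray(parc.labels.data)
    rows = []
    for rid in parc.region_ids:
        idx = np.argwhere(data == rid)
        if len(idx) == 0:
            rows.append({"id": int(rid), "x": np.nan, "y": np.nan, "z": np.nan,
                         "n_voxels": 0})
            continue
        pts = parc.labels.voxel_to_world(idx)
        m = _medoid_index(pts)
        rows.append({"id": int(rid), "x": pts[m, 0], "y": pts[m, 1],
                     "z": pts[m, 2], "n_voxels": len(idx)})
    return pd.DataFrame(rows).set_index("id")


def _medoid_index(pts: np.ndarray, chunk: int = 512) -> int:
    """Exact argmin of summed pairwise distance, chunked O(n^2).

    Distances are accumulated in single precision (inputs are voxel
    centres, well within float32 range) which halves the dominant cost.
    """
    p = np.asarray(pts, np.float32)
    n = len(p)
    total = np.zeros(n, np.float64)
    for s in range(0, n, chunk):
        d2 = ((p[s:s + chunk, None, :] - p[None, :, :]) ** 2).sum(axis=2)
        total[s:s + chunk] = np.sqrt(d2, out=d2).sum(axis=1)
    return int(np.argmin(total))  # argmin takes the first (lowest index) tie


def medoid_discrepancy(a: pd.DataFrame, b: pd.DataFrame) -> tuple:
    """Per-region Euclidean distances between two medoid tables.

    Returns ``(per_region, summary)`` where summary holds the median and
    the median absolute deviation across regions (mm).
    """
    if set(a.index) != set(b.index):
        bad = sorted(set(a.index) ^ set(b.index))
        raise ValueError(f"region id mismatch: {bad}")
    b = b.loc[a.index]
    d = np.linalg.norm(a[["x", "y", "z"]].to_numpy()
                       - b[["x", "y", "z"]].to_numpy(), axis=1)
    per_region = pd.DataFrame({"distance_mm": d}, index=a.index)
    valid = d[np.isfinite(d)]
    med = float(np.median(valid))
    mad = float(np.median(np.abs(valid - med)))
    return per_region, {"median_mm": med, "mad_mm": mad}


def isolate_coregistration_error(individual_brain: VoxelVolume,
                                 pseudo_brain: VoxelVolume,
                                 config: RegistrationConfig | None = None
                                 ) -> RigidTransform:
    """Rigid (6-DOF) brain-to-brain alignment.

    Aligning the individual brain into the pseudo-MRI frame lets both
    analyses reuse a single sensor coregistration, removing
    coregistration error from the comparison and leaving only anatomy
    (volume-conductor and region-definition) differences.
    """
    config = config or RegistrationConfig(dof=6)
    if config.dof != 6:
        raise ValueError("coregistration-error isolation is rigid (dof=6)")
    reg = registration.optimize_affine(individual_brain, pseudo_brain, config)
    return reg.transform
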