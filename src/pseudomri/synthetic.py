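"""Digital head phantoms with known ground truth.

The generator emulates every input of the real pipeline: a layered
head-like anatomy (scalp / skull / brain as perturbed nested
ellipsoids), a Voronoi "cortical" parcellation, noisy cropped
structured-light surface scans, triaxial OPM helmet arrays, a sensory
paradigm schedule, and MEG recordings containing beta-band
event-related desynchronisation, envelope-correlated source networks,
white sensor noise and homogeneous interference. All randomness is
driven by an explicit seed, and generator parameters can be serialised
to a sidecar JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import signal
from scipy.spatial import cKDTree

from .forward import ConductorModel, SingleShellModel, _sarvas_gains, _MM
from .geometry import (PointCloud, TriangleMesh, VoxelVolume,
                       extract_outer_surface, sample_surface_points)
from .preprocess import Recording
from .sensors import SensorArray
from .warp import Parcellation


@dataclass
class PlantedSource:
    """One dipolar source with optional task modulation and envelope group."""

    location: np.ndarray  # mm, anatomy frame
    orientation: np.ndarray  # unit vector
    amplitude: float = 20e-9  # A.m (20 nAm)
    erd_depth: float = 0.0  # fractional beta-amplitude drop during stimulation
    conditions: tuple = ("index", "little")  # conditions that modulate it
    envelope_rho: float = 0.0  # correlation with the shared envelope factor
    envelope_group: int = -1  # sources sharing a group id share the factor


@dataclass
class PhantomGroundTruth:
    anatomy: VoxelVolume
    scalp: TriangleMesh
    brain_mask: VoxelVolume
    parcellation: Parcellation
    seed: int
    true_affine: np.ndarray | None = None  # template -> subject, when derived
    sources: list = field(default_factory=list)
    interference: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    def save_sidecar(self, path) -> None:
        meta = {"seed": self.seed, "params": self.params,
                "sources": [{k: (v.tolist() if isinstance(v, np.ndarray) else v)
                             for k, v in asdict(s).items()} for s in self.sources],
                "interference": self.interference}
        with open(path, "w") as f:
            json.dump(meta, f, indent=2)


@dataclass
class ParadigmSchedule:
    """Alternating-condition stimulation schedule."""

    events: pd.DataFrame  # onset_s, condition
    stim_s: float
    rest_s: float
    total_s: float

    def __post_init__(self):
        on = self.events["onset_s"].to_numpy()
        if (np.diff(on) <= 0).any():
            raise ValueError("event onsets must be strictly increasing")


def make_paradigm(n_per_condition: int = 41, stim_s: float = 0.5,
                  rest_s: float = 3.0,
                  conditions=("index", "little")) -> ParadigmSchedule:
    """Alternating index/little stimulation; defaults give 82 trials
    over 287 s (0.5 s stimulation + 3 s rest per trial)."""
    if stim_s <= 0 or rest_s <= 0:
        raise ValueError("durations must be positive")
    n = n_per_condition * len(conditions)
    onsets = np.arange(n) * (stim_s + rest_s)
    conds = [conditions[i % len(conditions)] for i in range(n)]
    ev = pd.DataFrame({"onset_s": onsets, "condition": conds})
    return ParadigmSchedule(ev, stim_s, rest_s, n * (stim_s + rest_s))


# ---------------------------------------------------------------------------
# anatomy
# ---------------------------------------------------------------------------

# T1-like layer intensities (arbitrary units) and layer thicknesses (mm)
_SCALP_I, _SKULL_I = 70.0, 20.0
_SKULL_DEPTH, _BRAIN_DEPTH = 6.0, 12.0


def _bump_field(dirs: np.ndarray, rng: np.random.Generator, n_bumps: int,
                amplitude: float) -> np.ndarray:
    """Smooth random radial perturbation (fractional) on the unit sphere."""
    out = np.zeros(len(dirs))
    for _ in range(n_bumps):
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        width = rng.uniform(0.3, 0.8)
        out += rng.uniform(-1, 1) * np.exp((dirs @ d - 1) / width ** 2)
    return amplitude * out


def _face_field(dirs: np.ndarray) -> np.ndarray:
    """Deterministic head-like asymmetries (fractional radius): a nose
    and chin protrusion anteriorly, a flattened occiput posteriorly.
    +y is anterior, +z superior."""
    def lobe(d, width):
        d = np.asarray(d, float)
        d = d / np.linalg.norm(d)
        return np.exp((dirs @ d - 1) / width ** 2)

    return (0.10 * lobe((0.0, 0.95, -0.30), 0.22)   # nose
            + 0.06 * lobe((0.0, 0.80, -0.60), 0.30)  # chin / jaw
            - 0.04 * lobe((0.0, -1.0, 0.15), 0.45))  # flat occiput


def make_phantom_anatomy(size: int = 96, voxel_mm: float = 2.0,
                         n_regions: int = 78, seed: int = 0) -> PhantomGroundTruth:
    """Layered head phantom with a cortical Voronoi parcellation.

    Scalp/skull/brain are nested ellipsoids (adult-like half-axes with
    per-seed size jitter) perturbed by a smooth random radial field;
    the parcellation divides the outer "cortical" brain shell into
    ``n_regions`` Voronoi cells of seeded interior points. Deterministic
    per seed.
    """
    rng = np.random.default_rng(seed)
    radii = np.array([72.0, 88.0, 80.0]) * rng.uniform(0.96, 1.04, 3)
    centre = np.full(3, (size - 1) * voxel_mm / 2)
    affine = np.diag([voxel_mm] * 3 + [1.0])

    idx = np.indices((size, size, size)).reshape(3, -1).T
    pts = idx * voxel_mm - centre
    r = np.linalg.norm(pts, axis=1)
    dirs = pts / np.maximum(r, 1e-9)[:, None]
    rho = 1.0 + _face_field(dirs) + _bump_field(dirs, rng, n_bumps=8,
                                                amplitude=0.02)
    r_eff = np.linalg.norm(pts / (radii * rho[:, None]), axis=1)

    rmean = radii.mean()
    data = np.zeros(len(pts))
    data[r_eff <= 1.0] = _SCALP_I
    data[r_eff <= 1.0 - _SKULL_DEPTH / rmean] = _SKULL_I
    brain_edge = 1.0 - _BRAIN_DEPTH / rmean
    brain = r_eff <= brain_edge
    # internal brain contrast in normalised (shape-relative) coordinates,
    # so structures correspond across subjects: a brighter white-matter
    # core, dark ventricles, and a dark interhemispheric fissure
    depth = 1.0 - r_eff / brain_edge  # 0 at brain surface, 1 at centre
    data[brain] = 80.0 + 45.0 * np.clip(depth[brain] * 2.5, 0, 1)
    nr = pts / (radii * rho[:, None])  # normalised head coordinates
    for sx in (-1, 1):
        vent = (((nr[:, 0] - sx * 0.12) / 0.08) ** 2
                + (nr[:, 1] / 0.28) ** 2 + ((nr[:, 2] - 0.05) / 0.12) ** 2) <= 1.0
        data[brain & vent] = 25.0
    fissure = brain & (np.abs(nr[:, 0]) < 0.02) & (nr[:, 2] > 0.1)
    data[fissure] = 40.0
    anatomy = VoxelVolume(data.reshape(size, size, size), affine)
    brain_mask = VoxelVolume(brain.reshape(size, size, size).astype(np.uint8),
                             affine)

    scalp = extract_outer_surface(anatomy, _SKULL_I / 2)

    # cortical shell: outer part of the brain
    shell = brain & (r_eff > (1.0 - _BRAIN_DEPTH / rmean) * 0.62)
    shell_pts = pts[shell]
    if n_regions > shell.sum():
        raise ValueError("more regions than cortical voxels")
    seeds = shell_pts[_farthest_point_indices(shell_pts, n_regions, rng)]
    label_of = cKDTree(seeds).query(shell_pts)[1] + 1
    labels = np.zeros(len(pts), int)
    labels[shell] = label_of
    parc = Parcellation(
        VoxelVolume(labels.reshape(size, size, size), affine),
        pd.DataFrame({"id": np.arange(1, n_regions + 1),
                      "name": [f"region_{i:02d}" for i in range(1, n_regions + 1)]}))

    return PhantomGroundTruth(
        anatomy, scalp, brain_mask, parc, seed,
        params={"size": size, "voxel_mm": voxel_mm, "radii_mm": radii.tolist(),
                "n_regions": n_regions})


def _farthest_point_indices(pts: np.ndarray, k: int,
                            rng: np.random.Generator) -> np.ndarray:
    chosen = [int(rng.integers(len(pts)))]
    d = np.linalg.norm(pts - pts[chosen[0]], axis=1)
    for _ in range(k - 1):
        nxt = int(np.argmax(d))
        chosen.append(nxt)
        d = np.minimum(d, np.linalg.norm(pts - pts[nxt], axis=1))
    return np.array(chosen)


def approximate_fiducials(points: np.ndarray) -> np.ndarray:
    """Five reproducible quasi-fiducials of a head surface: the nose
    tip, upper occiput, left/right temporal extremes and the vertex.

    Stands in for the manual feature clicks of an operator. Lateral and
    posterior extremes are taken on the upper head (above the 35th
    height percentile) so the same anatomical ridges are found whether
    or not the lower face/neck was cropped from the scan. Assumes an
    approximately upright head (+z superior, +y anterior), as delivered
    by a head scanner."""
    p = np.atleast_2d(points)
    up = p[p[:, 2] >= np.percentile(p[:, 2], 35)]
    return np.array([p[np.argmax(p[:, 1])],    # nose tip
                     up[np.argmin(up[:, 1])],  # occiput
                     up[np.argmax(up[:, 0])],  # right temporal
                     up[np.argmin(up[:, 0])],  # left temporal
                     p[np.argmax(p[:, 2])]])   # vertex


# ---------------------------------------------------------------------------
# structured-light scan simulator
# ---------------------------------------------------------------------------


def simulate_headscan(scalp: TriangleMesh, distortion=None, noise_sd: float = 0.0,
                      crop_plane: tuple | None = None, cap_offset: float = 0.0,
                      n_points: int = 10000, seed: int = 0) -> PointCloud:
    """Noisy surface point cloud emulating a structured-light scan.

    Points are sampled uniformly by face area, offset along the local
    normal by ``cap_offset`` (an elastic-cap / residual-hair layer),
    jittered by isotropic Gaussian noise of ``noise_sd`` mm, mapped
    through the ``distortion`` transform (scanner frame), and finally
    cropped to the positive side of ``crop_plane = (point, normal)``.
    """
    rng = np.random.default_rng(seed)
    pts, normals = sample_surface_points(scalp, n_points, rng)
    pts = pts + cap_offset * normals + rng.normal(0, max(noise_sd, 0),
                                                  (n_points, 3))
    if distortion is not None:
        pts = distortion.apply(pts)
    cloud = PointCloud(pts)
    if crop_plane is not None:
        from .geometry import crop_below_plane
        cloud = crop_below_plane(cloud, *crop_plane)
    return cloud


# ---------------------------------------------------------------------------
# OPM helmet array
# ---------------------------------------------------------------------------


def place_opm_array(scalp: TriangleMesh, n_sensors: int = 64,
                    standoff: float = 6.5, seed: int = 0) -> SensorArray:
    """Approximately uniform triaxial OPM array over the scalp.

    Sensor sites are farthest-point samples of the scalp vertices,
    offset outward along the vertex normal by ``standoff`` mm (sensor
    cell standoff); each sensor carries an orthonormal triad with one
    axis along the local outward normal and yields three channels, so
    64 sensors give 192 channels.
    """
    if n_sensors < 4:
        raise ValueError("need at least 4 sensors")
    verts = scalp.vertices
    if n_sensors > len(verts):
        raise ValueError("more sensors than scalp vertices")
    rng = np.random.default_rng(seed)
    tm = scalp.to_trimesh()
    vnorm = np.array(tm.vertex_normals)
    centre = verts.mean(axis=0)
    out = np.einsum("ij,ij->i", vnorm, verts - centre) < 0
    vnorm[out] *= -1
    # keep sensors on the upper part of the head (no chin/neck sites)
    zcut = np.percentile(verts[:, 2], 25)
    cand = np.flatnonzero(verts[:, 2] > zcut)
    sites = cand[_farthest_point_indices(verts[cand], n_sensors, rng)]

    pos, ori, labels, sid = [], [], [], []
    for s, vi in enumerate(sites):
        n = vnorm[vi] / np.linalg.norm(vnorm[vi])
        t1 = np.cross(n, [0.0, 0.0, 1.0])
        if np.linalg.norm(t1) < 1e-6:
            t1 = np.cross(n, [0.0, 1.0, 0.0])
        t1 /= np.linalg.norm(t1)
        t2 = np.cross(n, t1)
        p = verts[vi] + standoff * n
        for ax, o in zip("ZXY", (n, t1, t2)):  # Z = radial axis
            pos.append(p)
            ori.append(o)
            labels.append(f"S{s:02d}-{ax}")
            sid.append(s)
    return SensorArray(np.array(pos), np.array(ori), labels, np.array(sid))


# ---------------------------------------------------------------------------
# recording simulator
# ---------------------------------------------------------------------------


def _beta_carrier(n: int, fs: float, rng: np.random.Generator,
                  band=(13.0, 30.0)) -> np.ndarray:
    """Non-phase-locked beta-band noise with unit mean envelope."""
    x = rng.normal(size=n)
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, x)
    env = np.abs(signal.hilbert(x))
    return x / env.mean()


def _smooth_gate(n: int, fs: float, onsets_s, stim_s: float, depth: float,
                 ramp_s: float = 0.1) -> np.ndarray:
    """Amplitude gate: 1 at rest, (1 - depth) during stimulation, with
    cosine ramps."""
    gate = np.ones(n)
    for on in onsets_s:
        i0, i1 = int(on * fs), int((on + stim_s) * fs)
        gate[i0:min(i1, n)] = 1 - depth
    w = int(max(ramp_s * fs, 1))
    kernel = np.hanning(2 * w + 1)
    kernel /= kernel.sum()
    return np.convolve(gate, kernel, mode="same")


def _slow_noise(n: int, fs: float, rng: np.random.Generator,
                cutoff: float = 1.0) -> np.ndarray:
    """Unit-variance low-frequency noise (envelope fluctuations,
    interference drift)."""
    x = rng.normal(size=n)
    sos = signal.butter(4, cutoff, btype="lowpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, x)
    sd = x.std()
    return x / sd if sd > 0 else x


def simulate_recording(gt: PhantomGroundTruth, sensors: SensorArray,
                       conductor: ConductorModel, paradigm: ParadigmSchedule,
                       fs: float = 1200.0, noise_sd: float | None = None,
                       snr: float | None = 5.0,
                       interference_amplitude: float = 0.0,
                       envelope_modulation: float = 0.3,
                       erd_extend_s: float = 0.3,
                       n_background: int = 100,
                       background_amp: float = 5e-9,
                       seed: int = 0) -> tuple:
    """Simulate an OPM recording from the phantom's planted sources.

    Each source emits beta-band noise whose envelope drops by its ERD
    depth during the stimulation windows of its conditions, optionally
    multiplied by a slowly varying envelope factor shared within its
    envelope group (pairwise envelope correlation ``rho``). Fields are
    projected through the conductor model; white sensor noise (set
    directly via ``noise_sd`` in tesla, or via ``snr`` = strongest
    channel signal RMS over noise SD) and a homogeneous interference
    field are added. Returns ``(Recording, truth)`` where ``truth``
    holds the exact source time courses and envelopes.

    All randomness derives from ``seed``; identical seeds give bitwise
    identical recordings.
    """
    rng = np.random.default_rng(seed)
    n = int(round(paradigm.total_s * fs))
    n_ch = sensors.n_channels
    data = np.zeros((n_ch, n))

    shell = SingleShellModel(conductor) if conductor.kind == "single_shell" else None
    if not gt.sources:
        raise ValueError("phantom has no planted sources")
    locs = np.array([s.location for s in gt.sources], float)
    if not conductor.contains(locs).all():
        raise ValueError("a planted source lies outside the conductor")

    shared = {}
    timecourses, envelopes = [], []
    for src in gt.sources:
        carrier = _beta_carrier(n, fs, rng)
        onsets = paradigm.events.loc[
            paradigm.events["condition"].isin(src.conditions), "onset_s"]
        # beta desynchronisation is sluggish: it persists ~erd_extend_s
        # beyond the stimulus before the envelope rebounds
        gate = _smooth_gate(n, fs, onsets.to_numpy(),
                            paradigm.stim_s + erd_extend_s,
                            src.erd_depth) if src.erd_depth else np.ones(n)
        env = np.ones(n)
        if src.envelope_group >= 0:
            if src.envelope_group not in shared:
                shared[src.envelope_group] = _slow_noise(n, fs, rng)
            rho = np.clip(src.envelope_rho, 0.0, 1.0)
            u = (np.sqrt(rho) * shared[src.envelope_group]
                 + np.sqrt(1 - rho) * _slow_noise(n, fs, rng))
            env = np.clip(1.0 + envelope_modulation * u, 0.05, None)
        q = src.amplitude * carrier * gate * env
        if conductor.kind == "sphere":
            gains = _sarvas_gains(
                (np.atleast_2d(src.location) - conductor.centre) * _MM,
                (sensors.positions - conductor.centre) * _MM,
                sensors.orientations)[0]  # (n_ch, 3)
            g = gains @ np.asarray(src.orientation, float)
        else:
            g = shell.field(src.location, np.asarray(src.orientation, float),
                            sensors, _check=False)
        data += np.outer(g, q)
        timecourses.append(q)
        envelopes.append(env * gate)

    signal_rms = np.sqrt((data ** 2).mean(axis=1)).max()
    if noise_sd is None:
        noise_sd = signal_rms / snr if (snr and signal_rms > 0) else 0.0

    # ongoing background brain activity: unmodulated broadband dipoles
    # scattered through the brain, so task contrasts are diluted away
    # from the planted sources as in real recordings
    if n_background > 0:
        bg_vox = np.argwhere(np.asarray(gt.brain_mask.data) > 0)
        picks = bg_vox[rng.choice(len(bg_vox), n_background, replace=False)]
        bg_loc = gt.brain_mask.voxel_to_world(picks)
        if conductor.kind == "sphere":
            keep = np.linalg.norm(bg_loc - conductor.centre, axis=1) \
                < 0.95 * conductor.radius
            bg_loc = bg_loc[keep]
        bg_ori = rng.normal(size=(len(bg_loc), 3))
        bg_ori /= np.linalg.norm(bg_ori, axis=1, keepdims=True)
        x = rng.normal(size=(len(bg_loc), n))
        sos = signal.butter(4, (2.0, min(100.0, 0.45 * fs)), btype="bandpass",
                            fs=fs, output="sos")
        x = signal.sosfiltfilt(sos, x, axis=1)
        x *= background_amp / x.std(axis=1, keepdims=True)
        if conductor.kind == "sphere":
            gains = _sarvas_gains((bg_loc - conductor.centre) * _MM,
                                  (sensors.positions - conductor.centre) * _MM,
                                  sensors.orientations)
            g_bg = np.einsum("sct,st->cs", gains, bg_ori)
        else:
            g_bg = np.stack([shell.field(l, o, sensors, _check=False)
                             for l, o in zip(bg_loc, bg_ori)], axis=1)
        data += g_bg @ x

    if noise_sd > 0:
        data += rng.normal(0, noise_sd, data.shape)
    if interference_amplitude > 0:
        b = np.stack([_slow_noise(n, fs, rng, cutoff=3.0) for _ in range(3)])
        data += sensors.orientations @ (interference_amplitude * b)

    samples = np.round(paradigm.events["onset_s"].to_numpy() * fs).astype(int)
    events = pd.DataFrame({"sample": samples,
                           "condition": paradigm.events["condition"]})
    rec = Recording(data, fs, [str(l) for l in sensors.labels], events)
    rec.log.append(f"simulated phantom recording seed={seed} fs={fs}")
    truth = {"timecourses": np.array(timecourses),
             "envelopes": np.array(envelopes),
             "noise_sd": float(noise_sd), "seed": seed}
    return rec, truth
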