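"""Rigid and affine registration of head surfaces and binary head masks.

Transforms are 4x4 homogeneous world-mm -> world-mm maps acting on column
vectors. The affine mask-to-mask registration mimics the classic
intensity-based approach: a correlation-ratio cost evaluated over the
overlap, optimised coarse-to-fine over 12 parameters (3 rotations,
3 translations, 3 scales, 3 shears).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize
from scipy.spatial import cKDTree

from .geometry import (DegenerateGeometryError, PointCloud, TriangleMesh,
                       VoxelVolume)


@dataclass
class AffineTransform:
    """Homogeneous 4x4 world->world transform, ``p' = M @ [p; 1]``."""

    matrix: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float).reshape(4, 4)
        if not np.allclose(self.matrix[3], (0, 0, 0, 1), atol=1e-9):
            raise ValueError("bottom row of an affine must be (0, 0, 0, 1)")
        if abs(np.linalg.det(self.matrix[:3, :3])) < 1e-12:
            raise ValueError("affine 3x3 block is singular")
        self.matrix[3] = (0, 0, 0, 1)

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(4))

    @property
    def rotation(self) -> np.ndarray:
        return self.matrix[:3, :3]

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:3, 3]

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, float))
        return pts @ self.matrix[:3, :3].T + self.matrix[:3, 3]

    def apply_vectors(self, vectors: np.ndarray, renormalise: bool = True) -> np.ndarray:
        """Map direction vectors through the rotation part only."""
        rot = _polar_rotation(self.matrix[:3, :3])
        out = np.atleast_2d(np.asarray(vectors, float)) @ rot.T
        if renormalise:
            out = out / np.linalg.norm(out, axis=-1, keepdims=True)
        return out

    def save(self, path) -> None:
        """Plain-text 4x4 row-major world->world matrix."""
        np.savetxt(str(path), self.matrix, fmt="%.12g")

    @classmethod
    def load(cls, path) -> "AffineTransform":
        return cls(np.loadtxt(str(path)))


class RigidTransform(AffineTransform):
    """Affine whose linear part is a proper rotation (R'R = I, det = +1)."""

    def __post_init__(self):
        super().__post_init__()
        R = self.matrix[:3, :3]
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise ValueError("rigid transform rotation is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rigid transform must not reflect")

    @classmethod
    def from_rotation_translation(cls, R: np.ndarray, t: np.ndarray) -> "RigidTransform":
        m = np.eye(4)
        m[:3, :3] = R
        m[:3, 3] = t
        return cls(m)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(4))


def compose(a: AffineTransform, b: AffineTransform) -> AffineTransform:
    """Transform applying ``b`` first, then ``a``:  p -> a(b(p))."""
    m = a.matrix @ b.matrix
    if isinstance(a, RigidTransform) and isinstance(b, RigidTransform):
        return RigidTransform(_reorthogonalise(m))
    return AffineTransform(m)


def invert(a: AffineTransform) -> AffineTransform:
    m = np.linalg.inv(a.matrix)
    if isinstance(a, RigidTransform):
        return RigidTransform(_reorthogonalise(m))
    return AffineTransform(m)


def _reorthogonalise(m: np.ndarray) -> np.ndarray:
    out = np.array(m, float)
    out[:3, :3] = _polar_rotation(out[:3, :3])
    out[3] = (0, 0, 0, 1)
    return out


def _polar_rotation(A: np.ndarray) -> np.ndarray:
    """Nearest proper rotation to a 3x3 matrix (polar decomposition)."""
    U, _, Vt = np.linalg.svd(A)
    R = U @ Vt
    if np.linalg.det(R) < 0:
        U[:, -1] *= -1
        R = U @ Vt
    return R


# ---------------------------------------------------------------------------
# rigid fitting
# ---------------------------------------------------------------------------


def fit_rigid_landmarks(src: np.ndarray, dst: np.ndarray) -> RigidTransform:
    """Least-squares rigid transform mapping paired landmarks src -> dst.

    Kabsch/Umeyama without scaling: minimises sum ||T(src_i) - dst_i||^2
    over rotations + translations. Requires >= 3 non-collinear pairs.
    """
    src = np.atleast_2d(np.asarray(src, float))
    dst = np.atleast_2d(np.asarray(dst, float))
    if src.shape != dst.shape or len(src) < 3:
        raise ValueError("need >= 3 corresponding landmark pairs")
    cs, cd = src.mean(axis=0), dst.mean(axis=0)
    X, Y = src - cs, dst - cd
    # collinearity check: second singular value of the centred cloud
    if np.linalg.svd(X, compute_uv=False)[1] < 1e-9 * max(1.0, np.abs(X).max()):
        raise DegenerateGeometryError("landmarks are collinear")
    R = _polar_rotation(Y.T @ X)
    return RigidTransform.from_rotation_translation(R, cd - R @ cs)


@dataclass
class ICPResult:
    transform: RigidTransform
    mean_distance: float
    n_iter: int
    converged: bool
    cost_history: list = field(default_factory=list)


def icp_refine(src: PointCloud, dst, init: RigidTransform | None = None,
               max_iter: int = 300, tol: float = 1e-6,
               max_points: int = 8000) -> ICPResult:
    """Iterative-closest-point rigid refinement of src onto dst.

    ``dst`` may be a point cloud or a triangle mesh (its vertices are
    used as the match set). Each iteration pairs every source point with
    its nearest destination point and solves the rigid Kabsch problem;
    iterations stop when the mean closest-point distance improves by less
    than ``tol`` mm. The accepted cost sequence is non-increasing.
    Sources larger than ``max_points`` are strided down: the rigid fit
    is heavily over-determined well below that.
    """
    if len(src) == 0:
        raise ValueError("source cloud is empty")
    dst_pts = dst.points if isinstance(dst, PointCloud) else dst.vertices
    tree = cKDTree(dst_pts)
    T = init if init is not None else RigidTransform.identity()
    src_pts = src.points
    if max_points and len(src_pts) > max_points:
        src_pts = src_pts[:: len(src_pts) // max_points + 1]
    src = PointCloud(src_pts)
    moved = T.apply(src.points)
    best = float(tree.query(moved)[0].mean())
    history = [best]
    converged = False
    for it in range(1, max_iter + 1):
        d, idx = tree.query(moved)
        step = fit_rigid_landmarks(moved, dst_pts[idx])
        cand_T = compose(step, T)
        cand_moved = cand_T.apply(src.points)
        cand_cost = float(tree.query(cand_moved)[0].mean())
        if cand_cost <= best:
            T, moved = cand_T, cand_moved
            improved = best - cand_cost
            best = cand_cost
            history.append(best)
            if improved < tol:
                converged = True
                break
        else:  # pairing no longer improves the rigid fit
            converged = True
            break
    return ICPResult(T, best, len(history) - 1, converged, history)


# ---------------------------------------------------------------------------
# intensity-based affine registration
# ---------------------------------------------------------------------------


@dataclass
class RegistrationConfig:
    """Parameters of the mask-to-mask affine registration.

    dof : 6 (rigid) or 12 (full affine: rotations, translations, scales,
        shears).
    rotation_bounds_deg : half-width of the admissible rotation range per
        axis; the coarse rotation seeding grid stays inside it.
    pyramid : downsampling factors, coarse to fine.
    bins : histogram bins for the correlation ratio; 2 is exact for
        binary masks.
    """

    dof: int = 12
    rotation_bounds_deg: float = 90.0
    pyramid: tuple = (4, 1)
    bins: int = 2
    tol: float = 1e-6
    interpolation: str = "trilinear"
    rotation_seed_step_deg: float = 30.0
    maxiter_per_level: tuple = (8, 6)
    boundary_band_vox: int | None = 3  # None: evaluate on the full grid
    domain: str = "band"  # "band" (mask surface shell), "support", "full"

    def __post_init__(self):
        if self.dof not in (6, 12):
            raise ValueError("dof must be 6 or 12")
        if len(self.pyramid) < 1:
            raise ValueError("pyramid needs >= 1 level")
        if self.interpolation not in ("trilinear", "nearest"):
            raise ValueError("interpolation must be trilinear or nearest")


def resample(volume: VoxelVolume, transform: AffineTransform,
             target: VoxelVolume, mode: str = "trilinear") -> VoxelVolume:
    """Pull-resample ``volume`` through a world->world transform.

    Each target voxel centre is mapped through the *inverse* transform
    into the source volume and interpolated (trilinear or nearest).
    Voxels mapping outside the source field of view are set to 0.
    """
    order = {"trilinear": 1, "nearest": 0}[mode]
    # target index -> source index:  A_s^-1 . T^-1 . A_t
    M = np.linalg.inv(volume.affine) @ np.linalg.inv(transform.matrix) @ target.affine
    out = ndimage.affine_transform(
        np.asarray(volume.data, float), M[:3, :3], offset=M[:3, 3],
        output_shape=target.shape, order=order, mode="constant", cval=0.0,
        prefilter=False)
    if mode == "nearest":
        out = out.astype(volume.data.dtype)
    return VoxelVolume(out, target.affine.copy())


def correlation_ratio(moving: VoxelVolume, fixed: VoxelVolume,
                      transform: AffineTransform, bins: int = 2) -> float:
    """Correlation-ratio registration cost in [0, 1].

    ``1 - (variance of fixed intensities explained by binned moving
    intensities)`` over the overlap of the two fields of view after
    mapping moving -> fixed through ``transform``. 0 means the moving
    image perfectly predicts the fixed one. A constant fixed image has
    no variance to explain and returns 0 by convention.
    """
    M = np.linalg.inv(moving.affine) @ np.linalg.inv(transform.matrix) @ fixed.affine
    idx = np.indices(fixed.shape).reshape(3, -1).T.astype(float)
    src = idx @ M[:3, :3].T + M[:3, 3]
    inb = ((src > -0.5) & (src < np.asarray(moving.shape) - 0.5)).all(axis=1)
    if not inb.any():
        raise ValueError("transformed fields of view do not overlap")
    mov_vals = ndimage.map_coordinates(np.asarray(moving.data, float),
                                       src[inb].T, order=1, mode="nearest")
    fix_vals = np.asarray(fixed.data, float).reshape(-1)[inb]
    return _correlation_ratio_values(mov_vals, fix_vals, bins)


def _correlation_ratio_values(mov: np.ndarray, fix: np.ndarray, bins: int) -> float:
    total_var = fix.var()
    if total_var <= 0:
        return 0.0
    lo, hi = mov.min(), mov.max()
    if hi <= lo:
        return 1.0  # constant predictor explains nothing
    which = np.clip(((mov - lo) / (hi - lo) * bins).astype(int), 0, bins - 1)
    n = np.bincount(which, minlength=bins)
    s = np.bincount(which, weights=fix, minlength=bins)
    s2 = np.bincount(which, weights=fix * fix, minlength=bins)
    nz = n > 0
    within = (s2[nz] - s[nz] ** 2 / n[nz]).sum() / len(fix)
    return float(np.clip(within / total_var, 0.0, 1.0))


# --- 12-parameter encoding ---------------------------------------------------

def params_to_matrix(p: np.ndarray, centre: np.ndarray) -> np.ndarray:
    """(tx ty tz rx ry rz log_sx log_sy log_sz kxy kxz kyz) -> 4x4.

    The linear part is ``R @ Shear @ Scale`` applied about ``centre`` so
    that rotations/scales do not translate the head off the grid.
    Rotations are in radians.
    """
    t, r, ls, k = p[0:3], p[3:6], p[6:9], p[9:12]
    cx, sx = np.cos(r[0]), np.sin(r[0])
    cy, sy = np.cos(r[1]), np.sin(r[1])
    cz, sz = np.cos(r[2]), np.sin(r[2])
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    shear = np.array([[1, k[0], k[1]], [0, 1, k[2]], [0, 0, 1]])
    A = Rz @ Ry @ Rx @ shear @ np.diag(np.exp(ls))
    m = np.eye(4)
    m[:3, :3] = A
    m[:3, 3] = t + centre - A @ centre
    return m


def _downsample_volume(vol: VoxelVolume, factor: int) -> VoxelVolume:
    if factor == 1:
        return vol
    sm = ndimage.uniform_filter(np.asarray(vol.data, float), size=factor)
    data = sm[factor // 2::factor, factor // 2::factor, factor // 2::factor]
    aff = np.eye(4)
    aff[:3, :3] = vol.affine[:3, :3] * factor
    aff[:3, 3] = vol.affine[:3, :3] @ np.full(3, factor // 2) + vol.affine[:3, 3]
    return VoxelVolume(data, aff)


class _CostEngine:
    """Correlation-ratio evaluator with the fixed-grid geometry cached.

    With ``band_vox`` set, the cost is evaluated only on fixed voxels
    within that many voxels of the fixed-mask boundary: for binary head
    masks all discriminative intensity structure sits at the surface, so
    this concentrates the cost there and cuts the evaluation cost by an
    order of magnitude.
    """

    def __init__(self, moving: VoxelVolume, fixed: VoxelVolume, bins: int,
                 band_vox: int | None = None, domain: str = "band",
                 max_eval: int = 40000):
        self.moving = np.asarray(moving.data, float)
        self.bins = bins
        self.inv_mov_affine = np.linalg.inv(moving.affine)
        idx = np.indices(fixed.shape).reshape(3, -1).T.astype(float)
        vals = np.asarray(fixed.data, float).reshape(-1)
        if band_vox and domain != "full":
            m = np.asarray(fixed.data) > 1e-6
            grown = ndimage.binary_dilation(m, iterations=band_vox)
            if domain == "band":  # surface shell only (binary masks)
                keep = grown & ~ndimage.binary_erosion(m, iterations=band_vox)
            else:  # "support": object + margin (grey-level images)
                keep = grown
            sel = np.flatnonzero(keep.reshape(-1))
            if len(sel) >= 1000:
                if len(sel) > max_eval:  # plenty of support: subsample
                    sel = sel[:: len(sel) // max_eval + 1]
                idx, vals = idx[sel], vals[sel]
        self.fixed_world_h = np.c_[idx @ fixed.affine[:3, :3].T + fixed.affine[:3, 3],
                                   np.ones(len(idx))]
        self.fixed_vals = vals
        self.upper = np.asarray(self.moving.shape, float) - 0.5

    def __call__(self, matrix: np.ndarray) -> float:
        M = self.inv_mov_affine @ np.linalg.inv(matrix)
        src = self.fixed_world_h @ M[:3].T
        inb = ((src > -0.5) & (src < self.upper)).all(axis=1)
        if not inb.any():
            return 1.0
        mov_vals = ndimage.map_coordinates(self.moving, src[inb].T, order=1,
                                           mode="nearest")
        return _correlation_ratio_values(mov_vals, self.fixed_vals[inb], self.bins)

    def residuals(self, matrix: np.ndarray) -> np.ndarray:
        """Intensity difference (moving under transform) - fixed, per
        evaluation voxel; out-of-field voxels read as 0."""
        M = self.inv_mov_affine @ np.linalg.inv(matrix)
        src = self.fixed_world_h @ M[:3].T
        mov_vals = ndimage.map_coordinates(self.moving, src.T, order=1,
                                           mode="constant", cval=0.0)
        return mov_vals - self.fixed_vals


@dataclass
class AffineRegistrationResult:
    transform: AffineTransform
    cost: float
    params: np.ndarray
    success: bool


def optimize_affine(moving: VoxelVolume, fixed: VoxelVolume,
                    config: RegistrationConfig | None = None,
                    init: AffineTransform | None = None) -> AffineRegistrationResult:
    """Mask-to-mask affine registration (moving -> fixed world frame).

    Strategy: (1) coarse rotation-grid seeding within the configured
    bounds combined with centroid matching; (2) a moment-matching affine
    initial guess (12 dof only); (3) derivative-free Powell refinement on
    a multi-resolution pyramid of the correlation-ratio cost. The
    returned cost never exceeds the cost of the initial transform.
    """
    config = config or RegistrationConfig()
    if (np.asarray(moving.data) > 0).sum() == 0 or (np.asarray(fixed.data) > 0).sum() == 0:
        raise ValueError("masks must be non-empty")
    init = init or AffineTransform.identity()
    centre = _mask_centroid(fixed)

    n_par = {6: 6, 12: 12}[config.dof]

    def expand(p):
        full = np.zeros(12)
        full[:n_par] = p
        return full

    engines = [_CostEngine(_downsample_volume(moving, f),
                           _downsample_volume(fixed, f), config.bins,
                           config.boundary_band_vox, config.domain)
               for f in config.pyramid]

    def cost_at(p, level):
        return engines[level](params_to_matrix(expand(p), centre))

    # -- initial parameter vector from the supplied init transform
    p0 = _matrix_to_params(init.matrix, centre, config.dof)[:n_par]
    init_cost = cost_at(p0, 0)

    # -- coarse seeding: rotation grid + centroid translation
    candidates = [p0]
    shift = _mask_centroid(fixed) - _mask_centroid(moving)
    bound = np.deg2rad(config.rotation_bounds_deg)
    step = np.deg2rad(config.rotation_seed_step_deg)
    angles = np.arange(-bound, bound + 1e-9, step)
    if len(angles) ** 3 <= 512:
        for rx in angles:
            for ry in angles:
                for rz in angles:
                    q = np.zeros(n_par)
                    q[0:3] = shift
                    q[3:6] = (rx, ry, rz)
                    candidates.append(q)

    # -- moment-matching affine guesses (often land within a voxel)
    fine_level = len(config.pyramid) - 1
    moment_cands = []
    white_m = white_f = None
    if config.dof == 12:
        # moments fix 9 of 12 dof; the skewness (third-moment) vectors
        # pin the remaining whitened rotation for asymmetric shapes
        try:
            white_m, white_f = _whitening(moving), _whitening(fixed)
            light = _CostEngine(moving, fixed, config.bins,
                                config.boundary_band_vox, config.domain,
                                max_eval=4000)
            mats = [_skewness_affine(moving, fixed, white_m, white_f)]
            mats += _whitened_rotation_search(moving, fixed, light,
                                              white_m, white_f, n_keep=2)
            moment_cands = [_matrix_to_params(m, centre, 12) for m in mats]
        except np.linalg.LinAlgError:
            pass
    # near-symmetric masks: coarse smoothing hides the features that
    # disambiguate orientation, so re-score the best coarse candidates —
    # and every moment-based fit — at the finest level before committing
    coarse = sorted(candidates, key=lambda q: cost_at(q, 0))
    best_p = min(coarse[:8] + moment_cands,
                 key=lambda q: cost_at(q, fine_level))

    # -- refinement: short derivative-free settling on the fine level,
    #    then a Gauss-Newton polish on Gaussian-smoothed masks (subvoxel)
    success = True
    p = np.asarray(best_p, float)
    if config.dof == 6:  # near-identity rigid cases: coarse-to-fine Powell
        maxiters = config.maxiter_per_level
        for level in range(len(config.pyramid)):
            mi = maxiters[min(level, len(maxiters) - 1)]
            res = optimize.minimize(
                cost_at, p, args=(level,), method="Powell",
                options={"xtol": config.tol, "ftol": config.tol, "maxiter": mi})
            if res.fun <= cost_at(p, level):
                p = res.x

    smooth_eng = _CostEngine(
        VoxelVolume(ndimage.gaussian_filter(np.asarray(moving.data, float), 1.0),
                    moving.affine),
        VoxelVolume(ndimage.gaussian_filter(np.asarray(fixed.data, float), 1.0),
                    fixed.affine),
        config.bins, config.boundary_band_vox, config.domain, max_eval=16000)

    def residuals(q):
        return smooth_eng.residuals(params_to_matrix(expand(q), centre))

    x_scale = np.r_[np.ones(3), np.full(9, 0.01)][:n_par]

    def polish(q):
        lsq = optimize.least_squares(residuals, q, method="lm",
                                     x_scale=x_scale, diff_step=1e-3,
                                     max_nfev=40 * n_par)
        return lsq.x if cost_at(lsq.x, fine_level) <= cost_at(q, fine_level) else q

    try:
        p = polish(p)
        if config.dof == 12 and cost_at(p, fine_level) > 0.07 \
                and white_m is not None:
            # chosen basin polishes badly: re-run the rotation search
            # with a denser grid and polish its candidates
            light = _CostEngine(moving, fixed, config.bins,
                                config.boundary_band_vox, config.domain,
                                max_eval=8000)
            try:
                extra = [_matrix_to_params(m, centre, 12)
                         for m in _whitened_rotation_search(
                             moving, fixed, light, white_m, white_f,
                             deep=True)]
            except np.linalg.LinAlgError:
                extra = []
            p = min([p] + [polish(np.asarray(c, float)) for c in extra],
                    key=lambda q: cost_at(q, fine_level))
    except Exception:  # noqa: BLE001 - polish is best-effort
        success = False

    # the polish minimises smoothed SSD; when the result is not already
    # essentially converged, settle onto the nearby local optimum of the
    # configured correlation-ratio cost itself
    if cost_at(p, fine_level) > 0.02 or config.dof == 6:
        res = optimize.minimize(
            cost_at, p, args=(fine_level,), method="Powell",
            options={"xtol": 1e-3, "ftol": 1e-4,
                     "maxiter": 1 if config.dof == 12 else 2})
        if res.fun <= cost_at(p, fine_level):
            p = res.x

    candidates_final = [p, best_p, p0]
    p = min(candidates_final, key=lambda q: cost_at(q, fine_level))
    final_cost = cost_at(p, fine_level)
    if np.array_equal(p, p0) and final_cost < cost_at(best_p, fine_level):
        success = False
    T = AffineTransform(params_to_matrix(expand(p), centre))
    if config.dof == 6:
        T = RigidTransform(_reorthogonalise(T.matrix))
    return AffineRegistrationResult(T, final_cost, expand(p), success)


def _mask_centroid(vol: VoxelVolume) -> np.ndarray:
    w = np.asarray(vol.data, float)
    idx = np.array(ndimage.center_of_mass(w))
    return vol.voxel_to_world(idx)[0]


def _mask_moments(vol: VoxelVolume):
    w = np.asarray(vol.data, float).reshape(-1)
    nz = np.flatnonzero(w)
    w = w[nz]
    shape = vol.shape
    idx = np.stack(np.unravel_index(nz, shape), axis=1).astype(float)
    pts = idx @ vol.affine[:3, :3].T + vol.affine[:3, 3]
    wsum = w.sum()
    mu = w @ pts / wsum
    d = pts - mu
    cov = (d.T * w) @ d / wsum
    return mu, cov

def _signed_permutations():
    """All 24 proper signed 3x3 permutation matrices (rotation group of
    the cube); resolves the principal-axes orientation ambiguity."""
    from itertools import permutations, product
    out = []
    for perm in permutations(range(3)):
        for signs in product((1, -1), repeat=3):
            P = np.zeros((3, 3))
            for i, (j, s) in enumerate(zip(perm, signs)):
                P[i, j] = s
            if np.linalg.det(P) > 0:
                out.append(P)
    return out


_SIGNED_PERMS = None


def _whitening(vol: VoxelVolume):
    """Centroid and symmetric whitening map of a mask's second moments.

    The *symmetric* inverse square root is used deliberately: it needs
    no eigenframe, so it stays stable when two moment eigenvalues are
    nearly degenerate, and the residual rotation between two whitened
    copies of the same shape is then close to the polar rotation of the
    true transform (small, for the transforms this package deals with)
    rather than an arbitrary eigenframe permutation.
    """
    mu, C = _mask_moments(vol)
    l, U = np.linalg.eigh(C)
    B = (U * (1.0 / np.sqrt(np.maximum(l, 1e-12)))) @ U.T
    return mu, B


def _boundary_points(vol: VoxelVolume, max_points: int = 1800) -> np.ndarray:
    """World coordinates of mask boundary voxel centres, subsampled."""
    m = np.asarray(vol.data) > 0.5
    edge = m & ~ndimage.binary_erosion(m)
    idx = np.argwhere(edge)
    if len(idx) > max_points:
        idx = idx[:: len(idx) // max_points + 1]
    return vol.voxel_to_world(idx)


def _whitened_rotation_search(moving: VoxelVolume, fixed: VoxelVolume,
                              light_engine, white_m=None, white_f=None,
                              n_keep: int = 3, deep: bool = False) -> list:
    """Candidate 4x4 affines from moment matching.

    Any transform ``A = B_f^{-1} R B_m`` (with B the symmetric whitening
    maps of the mask second moments, R a rotation) matches centroids and
    second moments exactly; the remaining 3-parameter rotation is the
    only unknown. With symmetric whitening it stays close to the polar
    rotation of the underlying transform, so a bounded two-level Euler
    grid (±40° at 8°, then ±6° at 3° around the best cells) followed by
    Powell covers it; the cost is evaluated on a subsampled set so the
    whole search costs a few thousand cheap evaluations.
    """
    mu_m, Bm = white_m if white_m is not None else _whitening(moving)
    mu_f, Bf_w = white_f if white_f is not None else _whitening(fixed)
    Bf_inv = np.linalg.inv(Bf_w)

    def matrix_of(rvec):
        A = Bf_inv @ _euler_matrix(rvec) @ Bm
        m = np.eye(4)
        m[:3, :3] = A
        m[:3, 3] = mu_f - A @ mu_m
        return m

    def cost(rvec):
        return light_engine(matrix_of(rvec))

    if deep:
        g = np.deg2rad(np.arange(-40.0, 40.1, 8.0))
        dg = np.deg2rad(np.arange(-6.0, 6.1, 3.0))
        n_local, n_powell, maxiter = 3, 4, 6
    else:
        g = np.deg2rad(np.arange(-40.0, 40.1, 10.0))
        dg = np.deg2rad(np.arange(-5.0, 5.1, 2.5))
        n_local, n_powell, maxiter = 2, 2, 4
    coarse = sorted(((cost((rx, ry, rz)), (rx, ry, rz))
                     for rx in g for ry in g for rz in g))
    local = list(coarse[:n_local])
    for c0, r0 in coarse[:n_local]:
        r0 = np.asarray(r0)
        for dx in dg:
            for dy in dg:
                for dz in dg:
                    r = r0 + (dx, dy, dz)
                    local.append((cost(r), tuple(r)))
    local.sort()
    refined = []
    for c0, r0 in local[:n_powell]:
        res = optimize.minimize(cost, np.asarray(r0), method="Powell",
                                options={"xtol": 1e-5, "maxiter": maxiter})
        refined.append((res.fun, res.x))
    refined.sort(key=lambda t: t[0])
    return [matrix_of(r) for _, r in refined[:n_keep]]


def _whitened_skew_stats(vol: VoxelVolume, white=None):
    mu, B = white if white is not None else _whitening(vol)
    w = np.asarray(vol.data, float).reshape(-1)
    nz = np.flatnonzero(w)
    w = w[nz]
    idx = np.stack(np.unravel_index(nz, vol.shape), axis=1).astype(float)
    pts = idx @ vol.affine[:3, :3].T + vol.affine[:3, 3]
    u = (pts - mu) @ B.T
    wsum = w.sum()
    r2 = (u ** 2).sum(axis=1)
    s1 = (w * r2) @ u / wsum
    proj = u @ s1
    s2 = (w * proj ** 2) @ u / wsum
    s3 = (w * r2 ** 2) @ u / wsum
    return mu, B, np.array([s1, s2, s3])


def _skewness_affine(moving: VoxelVolume, fixed: VoxelVolume,
                     white_m=None, white_f=None) -> np.ndarray:
    """Deterministic moment initialisation using shape asymmetry.

    Second moments fix the transform up to a rotation in whitened
    coordinates; that rotation is estimated by Kabsch alignment of
    rotation-equivariant third-order (skewness) moment vectors, which a
    head's facial asymmetry determines well.
    """
    mu_m, Bm, Sm = _whitened_skew_stats(moving, white_m)
    mu_f, Bf_w, Sf = _whitened_skew_stats(fixed, white_f)
    R = _polar_rotation(Sf.T @ Sm)
    A = np.linalg.inv(Bf_w) @ R @ Bm
    m = np.eye(4)
    m[:3, :3] = A
    m[:3, 3] = mu_f - A @ mu_m
    return m


def _euler_matrix(r) -> np.ndarray:
    cx, sx = np.cos(r[0]), np.sin(r[0])
    cy, sy = np.cos(r[1]), np.sin(r[1])
    cz, sz = np.cos(r[2]), np.sin(r[2])
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


def _matrix_to_params(m: np.ndarray, centre: np.ndarray, dof: int) -> np.ndarray:
    """Invert :func:`params_to_matrix` (best effort for the rigid part)."""
    A = m[:3, :3]
    if dof == 12:
        # A = Q @ U with Q a proper rotation and U upper triangular with
        # positive diagonal: exactly the R @ Shear @ Scale factorisation.
        Q, U = np.linalg.qr(A)
        signs = np.sign(np.diag(U))
        signs[signs == 0] = 1.0
        Q, U = Q * signs, U * signs[:, None]
        if np.linalg.det(Q) < 0:  # reflections are outside the model
            Q, U = _polar_rotation(A), None
        R = Q
    else:
        R = _polar_rotation(A)
        U = None
    # R = Rz Ry Rx euler extraction
    ry = np.arcsin(np.clip(-R[2, 0], -1, 1))
    if abs(np.cos(ry)) > 1e-8:
        rx = np.arctan2(R[2, 1], R[2, 2])
        rz = np.arctan2(R[1, 0], R[0, 0])
    else:  # gimbal lock
        rx = np.arctan2(-R[1, 2], R[1, 1])
        rz = 0.0
    p = np.zeros(12)
    p[3:6] = (rx, ry, rz)
    if dof == 12:
        if U is None:
            U = R.T @ A
        sc = np.diag(U).copy()
        sc[sc <= 0] = 1e-6
        p[6:9] = np.log(sc)
        p[9] = U[0, 1] / sc[1]
        p[10] = U[0, 2] / sc[2]
        p[11] = U[1, 2] / sc[2]
    lin = params_to_matrix(p, centre)[:3, :3]
    p[0:3] = m[:3, 3] - (centre - lin @ centre)
    return p
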