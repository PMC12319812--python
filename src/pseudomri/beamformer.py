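"""LCMV beamforming: covariance estimation, Tikhonov regularisation,
orientation optimisation, pseudo-T contrast images and virtual
electrodes.

The scalar LCMV spatial filter for a forward vector ``l`` and data
covariance ``C`` is ``w = C^-1 l / (l^T C^-1 l)`` (unit gain at the
target, minimum variance elsewhere). Source orientation at each
candidate location is chosen to maximise projected power, i.e. the
generalised "optimal orientation" given by the smallest eigenvector of
``L^T C^-1 L``. Task modulation is summarised by a pseudo-T contrast
``(P_active - P_control) / (P_active + P_control)``, a bounded,
depth-bias-cancelling normalisation; beta-band desynchronisation
appears as negative values, so image extrema are taken at the most
negative voxel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .forward import LeadField, SourceSpace
from .preprocess import TrialSet


@dataclass
class CovarianceMatrix:
    matrix: np.ndarray
    window: tuple | None = None
    conditions: tuple | None = None
    regularisation: float = 0.0
    n_samples: int = 0

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValueError("covariance must be square")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-12 * max(
                1.0, np.abs(self.matrix).max())):
            raise ValueError("covariance must be symmetric")
        self.matrix = 0.5 * (self.matrix + self.matrix.T)

    @property
    def inv(self) -> np.ndarray:
        if not hasattr(self, "_inv"):
            self._inv = np.linalg.inv(self.matrix)
        return self._inv


@dataclass
class PseudoTImage:
    values: np.ndarray
    source_space: SourceSpace
    active_window: tuple
    control_window: tuple
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        if len(self.values) != len(self.source_space):
            raise ValueError("value count must match the source space")
        if not np.isfinite(self.values).all():
            raise ValueError("pseudo-T image contains non-finite values")

    @property
    def peak_index(self) -> int:
        """Most negative voxel (beta desynchronisation); ties break to
        the lowest source index."""
        return int(np.argmin(self.values))

    @property
    def peak_location(self) -> np.ndarray:
        return self.source_space.points[self.peak_index]


# ---------------------------------------------------------------------------


def compute_covariance(ts: TrialSet, window: tuple | None = None,
                       conditions=None) -> CovarianceMatrix:
    """Data covariance over retained trials restricted to a time window.

    The channel mean is removed per trial-window; windows are then
    concatenated and ``C = X X^T / (n - 1)`` computed over all samples.
    """
    keep = ts.select(conditions)
    if not keep.any():
        raise ValueError("no retained trials match the selection")
    sl = ts.window_slice(*window) if window is not None else slice(None)
    segs = ts.data[keep][:, :, sl]
    segs = segs - segs.mean(axis=2, keepdims=True)
    X = np.concatenate(list(segs), axis=1)
    n = X.shape[1]
    if n < 2:
        raise ValueError("window too short for covariance")
    C = X @ X.T / (n - 1)
    win = (float(ts.times[sl][0]), float(ts.times[sl][-1])) if window else None
    return CovarianceMatrix(C, win, tuple(np.unique(
        [c for c, k in zip(ts.conditions, keep) if k])), 0.0, n)


def regularize_tikhonov(C: CovarianceMatrix, fraction: float = 0.05) -> CovarianceMatrix:
    """``C + lambda I`` with lambda = fraction x largest eigenvalue."""
    lam = fraction * float(np.linalg.eigvalsh(C.matrix)[-1]) if fraction else 0.0
    out = CovarianceMatrix(C.matrix + lam * np.eye(len(C.matrix)), C.window,
                           C.conditions, lam, C.n_samples)
    return out


def optimal_orientation(L: np.ndarray, Cinv: np.ndarray) -> np.ndarray:
    """Unit orientation maximising noise-normalised projected power.

    The source power seen through the unit-gain filter for orientation
    eta, normalised by the projected sensor-noise power, is the
    generalised Rayleigh quotient ``(eta^T A eta) / (eta^T B eta)`` with
    ``A = L^T C^-1 L`` and ``B = L^T C^-2 L``; the optimum is the
    generalised eigenvector with the largest eigenvalue. A tiny ridge on
    B rejects silent orientations (e.g. the radial direction of a
    spherical conductor, where the lead field vanishes) and reduces to
    the dominant right-singular direction of L when A and B are
    proportional (white covariance). Sign convention: positive first
    non-negligible component.
    """
    L = np.asarray(L, float)
    if np.linalg.matrix_rank(L) < 2:
        raise ValueError("forward matrix is rank deficient")
    CL = Cinv @ L
    A = L.T @ CL
    B = CL.T @ CL
    eps = 1e-8 * np.trace(B) / 3.0
    from scipy.linalg import eigh
    _, vecs = eigh(0.5 * (A + A.T), 0.5 * (B + B.T) + eps * np.eye(3))
    eta = vecs[:, -1]
    nz = np.flatnonzero(np.abs(eta) > 1e-12)
    if len(nz) and eta[nz[0]] < 0:
        eta = -eta
    return eta / np.linalg.norm(eta)


def lcmv_weights(l: np.ndarray, Cinv: np.ndarray) -> np.ndarray:
    """Unit-gain minimum-variance weights ``C^-1 l / (l^T C^-1 l)``."""
    l = np.asarray(l, float).reshape(-1)
    Cl = Cinv @ l
    denom = float(l @ Cl)
    if denom <= 0:
        raise ValueError("degenerate forward vector (l^T C^-1 l <= 0)")
    return Cl / denom


def _batched_orientations_weights(lf: LeadField, Cinv: np.ndarray):
    """Optimal orientation and unit-gain weights for every source.

    Vectorised version of :func:`optimal_orientation` +
    :func:`lcmv_weights`: the generalised eigenproblem (A, B + eps I) is
    reduced to a standard one with batched Cholesky factors.
    """
    L = lf.gains  # (S, C, 3)
    CL = np.einsum("ij,sjk->sik", Cinv, L)  # C^-1 L
    A = np.einsum("sji,sjk->sik", L, CL)  # L^T C^-1 L
    B = np.einsum("sji,sjk->sik", CL, CL)  # L^T C^-2 L
    A = 0.5 * (A + np.transpose(A, (0, 2, 1)))
    B = 0.5 * (B + np.transpose(B, (0, 2, 1)))
    eps = 1e-8 * np.einsum("sii->s", B) / 3.0
    B = B + eps[:, None, None] * np.eye(3)
    F = np.linalg.cholesky(B)
    Finv = np.linalg.inv(F)
    M = Finv @ A @ np.transpose(Finv, (0, 2, 1))
    _, vecs = np.linalg.eigh(0.5 * (M + np.transpose(M, (0, 2, 1))))
    y = vecs[:, :, -1]  # largest noise-normalised power
    eta = np.einsum("sij,sj->si", np.transpose(Finv, (0, 2, 1)), y)
    eta = eta / np.linalg.norm(eta, axis=1, keepdims=True)
    l = np.einsum("scj,sj->sc", L, eta)
    Cl = np.einsum("ij,sj->si", Cinv, l)
    denom = np.einsum("sc,sc->s", l, Cl)
    w = Cl / denom[:, None]
    return eta, w


def pseudo_t_map(lf: LeadField, ts: TrialSet, active: tuple, control: tuple,
                 C: CovarianceMatrix, conditions=None) -> PseudoTImage:
    """Pseudo-T contrast of source power between active and control
    windows for every source in the lead field.

    Orientations and weights come from the supplied (regularised)
    full-window covariance ``C``; window powers are ``w^T C_win w`` with
    unregularised window covariances.
    """
    Ca = compute_covariance(ts, active, conditions).matrix
    Cc = compute_covariance(ts, control, conditions).matrix
    _, W = _batched_orientations_weights(lf, C.inv)
    Pa = np.einsum("sc,cd,sd->s", W, Ca, W)
    Pc = np.einsum("sc,cd,sd->s", W, Cc, W)
    T = (Pa - Pc) / (Pa + Pc)
    return PseudoTImage(T, lf.source_space, tuple(active), tuple(control),
                        meta={"formula": "(Pa-Pc)/(Pa+Pc)",
                              "regularisation": C.regularisation,
                              "conditions": conditions})


def virtual_electrode(location, lf: LeadField, ts: TrialSet,
                      C: CovarianceMatrix, conditions=None,
                      normalise: bool = True) -> np.ndarray:
    """Beamformer-reconstructed source time course at one location.

    Weights use the supplied (typically broadband) covariance at the
    location's optimal orientation, applied to every retained trial.
    With ``normalise`` the weights are divided by their norm, giving a
    noise-normalised amplitude scale.
    """
    idx = lf.source_space.nearest(location)
    if np.linalg.norm(lf.source_space.points[idx] - np.asarray(location, float)) \
            > lf.source_space.spacing * 1.5:
        raise ValueError("location lies outside the source space")
    eta = optimal_orientation(lf.gains[idx], C.inv)
    w = lcmv_weights(lf.gains[idx] @ eta, C.inv)
    if normalise:
        w = w / np.linalg.norm(w)
    keep = ts.select(conditions)
    return np.einsum("c,tcs->ts", w, ts.data[keep])
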