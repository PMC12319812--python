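"""Hilbert-envelope spectrograms and amplitude-envelope-correlation
(AEC) connectomics.

Regional beta-band signals are reduced to amplitude envelopes via the
analytic signal; zero-lag linear leakage between beamformed regional
time courses is suppressed by pairwise orthogonalisation before the
envelopes are correlated. The connectome is symmetrised by averaging
the two orthogonalisation directions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import hilbert

from .preprocess import bandpass_array


@dataclass
class TimeFrequencySpectrogram:
    """Bands x time matrix of relative amplitude change from baseline."""

    values: np.ndarray
    band_centres: np.ndarray
    band_edges: np.ndarray  # (n_bands, 2)
    times: np.ndarray
    baseline: tuple

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        self.band_centres = np.asarray(self.band_centres, float)
        self.band_edges = np.asarray(self.band_edges, float).reshape(-1, 2)
        self.times = np.asarray(self.times, float)
        if self.values.shape != (len(self.band_centres), len(self.times)):
            raise ValueError("TFS shape must be bands x time")
        if (self.band_edges <= 0).any() or (
                self.band_edges[:, 0] >= self.band_edges[:, 1]).any():
            raise ValueError("band edges must be positive with low < high")

    def band_rows(self, lo: float, hi: float) -> np.ndarray:
        return np.flatnonzero((self.band_centres >= lo) & (self.band_centres <= hi))


@dataclass
class Connectome:
    """Symmetric region x region AEC matrix, zero diagonal."""

    matrix: np.ndarray
    region_ids: np.ndarray
    band: tuple | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, float)
        self.region_ids = np.asarray(self.region_ids)
        r = len(self.region_ids)
        if self.matrix.shape != (r, r):
            raise ValueError("matrix shape must match region ids")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-12):
            raise ValueError("connectome must be symmetric")
        if np.abs(np.diag(self.matrix)).max() > 1e-12:
            raise ValueError("connectome diagonal must be zero")
        if np.abs(self.matrix).max() > 1.0 + 1e-9:
            raise ValueError("correlations must lie in [-1, 1]")

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    def to_csv(self, path) -> None:
        pd.DataFrame(self.matrix, index=self.region_ids,
                     columns=self.region_ids).to_csv(path)


# ---------------------------------------------------------------------------


def hilbert_envelope(x: np.ndarray, axis: int = -1) -> np.ndarray:
    """Amplitude envelope: magnitude of the analytic signal."""
    return np.abs(hilbert(np.asarray(x, float), axis=axis))


def default_bands(lo: float = 3.0, hi: float = 99.0, step: float = 2.0,
                  half_width: float = 2.5) -> np.ndarray:
    """Overlapping band set (centre - hw, centre + hw) for the TFS."""
    centres = np.arange(lo, hi + 1e-9, step)
    return np.c_[centres, centres - half_width, centres + half_width]


def trial_tfs(ve: np.ndarray, rate: float, times: np.ndarray,
              baseline: tuple, bands: np.ndarray | None = None) -> TimeFrequencySpectrogram:
    """Time-frequency spectrogram of a virtual-electrode trial set.

    Per band: zero-phase bandpass, Hilbert envelope per trial, average
    across trials, then express as relative change from the mean
    envelope in the baseline window, (E - B) / B.
    """
    ve = np.atleast_2d(np.asarray(ve, float))  # trials x samples
    times = np.asarray(times, float)
    bands = bands if bands is not None else default_bands()
    bands = np.asarray(bands, float)
    bmask = (times >= baseline[0] - 1e-9) & (times <= baseline[1] + 1e-9)
    if not bmask.any():
        raise ValueError("baseline window outside the trial")
    nyq = rate / 2
    out = np.empty((len(bands), ve.shape[1]))
    for i, (c, lo, hi) in enumerate(bands):
        hi = min(hi, nyq * 0.99)
        filt = bandpass_array(ve, lo, hi, rate)
        env = hilbert_envelope(filt, axis=1).mean(axis=0)
        b = env[bmask].mean()
        if b <= 0:
            raise ValueError("baseline envelope mean is zero")
        out[i] = (env - b) / b
    return TimeFrequencySpectrogram(out, bands[:, 0], bands[:, 1:], times,
                                    tuple(baseline))


def orthogonalize_pair(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Residual of y after removing its zero-lag projection on x."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xx = float(x @ x)
    if xx <= 0:
        raise ValueError("cannot orthogonalise against a zero signal")
    return y - x * (float(x @ y) / xx)


def block_downsample(x: np.ndarray, rate: float, target: float = 120.0) -> np.ndarray:
    """Non-overlapping block means down to the target rate (last axis)."""
    step = int(round(rate / target))
    if step <= 1:
        return np.asarray(x, float)
    n = (x.shape[-1] // step) * step
    return np.asarray(x, float)[..., :n].reshape(*x.shape[:-1], -1, step).mean(axis=-1)


def aec_connectome(regional: np.ndarray, rate: float, region_ids=None,
                   envelope_rate: float = 120.0,
                   both_directions: bool = True) -> Connectome:
    """Orthogonalised amplitude-envelope-correlation connectome.

    ``regional`` is regions x samples of band-limited (beta) signals,
    trials already cropped and concatenated. For each ordered pair the
    target is orthogonalised on the seed, both envelopes are block-
    averaged to ``envelope_rate`` and Pearson-correlated; the matrix is
    symmetrised by averaging the two directions. Pairs with a constant
    envelope are recorded as 0 with a warning.
    """
    X = np.atleast_2d(np.asarray(regional, float))
    R = X.shape[0]
    if R < 2:
        raise ValueError("need at least 2 regions")
    ids = np.asarray(region_ids) if region_ids is not None else np.arange(R)
    # single precision: envelopes are correlated, not integrated, so
    # float32 is ample and halves the dominant memory traffic
    analytic = hilbert(X, axis=1).astype(np.complex64)
    norms2 = np.einsum("rs,rs->r", X, X)
    a_norm2 = (np.abs(analytic) ** 2).sum(axis=1)
    out = np.zeros((R, R))
    degenerate = False
    for i in range(R):
        if norms2[i] <= 0:
            degenerate = True
            continue
        coef = ((X @ X[i]) / norms2[i]).astype(np.float32)
        resid_analytic = analytic - coef[:, None] * analytic[i]
        # a residual that is numerically zero relative to the original is
        # pure rounding noise whose envelope still mimics the seed's;
        # treat it as degenerate rather than correlating it
        resid_frac = np.sqrt((np.abs(resid_analytic) ** 2).sum(axis=1)
                             / np.maximum(a_norm2, 1e-300))
        env_j = block_downsample(np.abs(resid_analytic), rate, envelope_rate)
        env_i = block_downsample(np.abs(analytic[i]), rate, envelope_rate)
        si = env_i.std()
        sj = env_j.std(axis=1)
        ok = (sj > 0) & (si > 0) & (resid_frac > 1e-6)
        ok[i] = False
        r = np.zeros(R)
        if si > 0:
            zi = env_i - env_i.mean()
            zj = env_j - env_j.mean(axis=1, keepdims=True)
            r[ok] = (zj[ok] @ zi) / (np.linalg.norm(zj[ok], axis=1)
                                     * np.linalg.norm(zi))
        degenerate = degenerate or (~ok[np.arange(R) != i]).any()
        out[i] = r  # row i: correlation of env(i) with env(j orth i)
    if degenerate:
        warnings.warn("constant envelope encountered; correlation set to 0")
    mat = 0.5 * (out + out.T) if both_directions else out
    mat = 0.5 * (mat + mat.T)
    np.fill_diagonal(mat, 0.0)
    return Connectome(np.clip(mat, -1, 1), ids,
                      meta={"envelope_rate": envelope_rate,
                            "orthogonalised": True})


def global_connectivity(c: Connectome) -> float:
    """Sum of all off-diagonal entries (both triangles)."""
    return float(c.matrix.sum() - np.trace(c.matrix))


def top_fraction_edges(c: Connectome, fraction: float = 0.05):
    """Strongest unique edges plus per-node strength (row sums).

    Returns ``(edges, strength)`` where ``edges`` is a DataFrame with
    columns (i, j, value) holding ``floor(fraction * R(R-1)/2)`` rows
    ranked by connectivity.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must lie in (0, 1]")
    R = c.n_regions
    iu = np.triu_indices(R, k=1)
    vals = c.matrix[iu]
    n_keep = int(np.floor(fraction * R * (R - 1) / 2))
    order = np.argsort(vals)[::-1][:n_keep]
    edges = pd.DataFrame({"i": c.region_ids[iu[0][order]],
                          "j": c.region_ids[iu[1][order]],
                          "value": vals[order]})
    strength = pd.Series(c.matrix.sum(axis=1), index=c.region_ids,
                         name="strength")
    return edges, strength


def compare_connectomes(a: Connectome, b: Connectome) -> float:
    """Pearson r between the vectorised upper triangles."""
    if a.n_regions != b.n_regions or not np.array_equal(a.region_ids, b.region_ids):
        raise ValueError("connectomes cover different regions")
    iu = np.triu_indices(a.n_regions, k=1)
    return float(np.corrcoef(a.matrix[iu], b.matrix[iu])[0, 1])
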