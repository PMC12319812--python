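"""OPM recording preprocessing: filtering, epoching, trial rejection and
homogeneous field correction (HFC).

The canonical order is recording-level: notch -> bandpass -> HFC ->
epoch -> variance-based trial rejection. Every step appends an entry to
the object's ``log`` so a processed dataset carries its own provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd
from scipy import signal

from .sensors import SensorArray


@dataclass
class Recording:
    """Continuous channels x samples data (tesla) with an event table.

    ``events`` is a DataFrame with integer ``sample`` and string
    ``condition`` columns.
    """

    data: np.ndarray
    rate: float = 1200.0
    labels: list = field(default_factory=list)
    events: pd.DataFrame | None = None
    log: list = field(default_factory=list)

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data, float))
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        if not self.labels:
            self.labels = [f"ch{i:03d}" for i in range(self.data.shape[0])]
        if self.events is None:
            self.events = pd.DataFrame({"sample": pd.Series(dtype=int),
                                        "condition": pd.Series(dtype=str)})
        bad = (self.events["sample"] < 0) | (self.events["sample"] >= self.data.shape[1])
        if bad.any():
            raise ValueError("event sample index outside the recording")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def copy_with(self, data, step=None) -> "Recording":
        rec = Recording(data, self.rate, list(self.labels),
                        self.events.copy(), list(self.log))
        if step:
            rec.log.append(step)
        return rec

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=self.data)
            f.attrs["rate"] = self.rate
            f.create_dataset("labels", data=np.array(self.labels, dtype="S"))
            f.create_dataset("event_sample", data=self.events["sample"].to_numpy(int))
            f.create_dataset("event_condition",
                             data=self.events["condition"].astype(str).to_numpy(dtype="S"))
            f.attrs["log"] = "\n".join(self.log)

    @classmethod
    def load(cls, path) -> "Recording":
        with h5py.File(path, "r") as f:
            ev = pd.DataFrame({
                "sample": f["event_sample"][()].astype(int),
                "condition": [s.decode() for s in f["event_condition"][()]]})
            rec = cls(f["data"][()], float(f.attrs["rate"]),
                      [s.decode() for s in f["labels"][()]], ev)
            rec.log = [s for s in str(f.attrs.get("log", "")).split("\n") if s]
        return rec


@dataclass
class TrialSet:
    """Epoched trials x channels x samples with retained flags."""

    data: np.ndarray
    times: np.ndarray
    conditions: list
    rate: float
    retained: np.ndarray = None
    log: list = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data, float)
        if self.data.ndim != 3:
            raise ValueError("trial data must be trials x channels x samples")
        self.times = np.asarray(self.times, float)
        if len(self.times) != self.data.shape[2]:
            raise ValueError("time axis must match the sample count")
        if self.retained is None:
            self.retained = np.ones(self.data.shape[0], bool)
        self.retained = np.asarray(self.retained, bool)
        self.conditions = list(self.conditions)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def select(self, conditions=None, retained_only: bool = True) -> np.ndarray:
        """Boolean index of trials matching the condition filter."""
        keep = self.retained.copy() if retained_only else np.ones(self.n_trials, bool)
        if conditions is not None:
            wanted = {conditions} if isinstance(conditions, str) else set(conditions)
            keep &= np.array([c in wanted for c in self.conditions])
        return keep

    def window_slice(self, t0: float, t1: float) -> slice:
        i0 = int(np.searchsorted(self.times, t0 - 1e-9))
        i1 = int(np.searchsorted(self.times, t1 + 1e-9))
        if i1 <= i0:
            raise ValueError("window does not overlap the trial time axis")
        return slice(i0, i1)


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------


def notch_filter(rec: Recording, freqs, quality: float = 30.0) -> Recording:
    """Zero-phase IIR notch at each frequency (e.g. mains + harmonics)."""
    nyq = rec.rate / 2
    data = rec.data.copy()
    for f0 in np.atleast_1d(freqs):
        if f0 >= nyq:
            raise ValueError(f"notch frequency {f0} Hz is at/above Nyquist")
        b, a = signal.iirnotch(f0, quality, fs=rec.rate)
        data = signal.filtfilt(b, a, data, axis=1)
    return rec.copy_with(data, f"notch {list(np.atleast_1d(freqs))} Hz")


def bandpass(rec: Recording, lo: float, hi: float, order: int = 4) -> Recording:
    """Butterworth bandpass applied forward-backward (zero phase).

    A 4th-order design run in both directions, i.e. an effective
    8th-order magnitude response with no phase distortion.
    """
    nyq = rec.rate / 2
    if not (0 < lo < hi < nyq):
        raise ValueError("band edges must satisfy 0 < lo < hi < Nyquist")
    sos = signal.butter(order, (lo, hi), btype="bandpass", fs=rec.rate, output="sos")
    data = signal.sosfiltfilt(sos, rec.data, axis=1)
    return rec.copy_with(data, f"bandpass {lo}-{hi} Hz order {order} zero-phase")


def bandpass_array(x: np.ndarray, lo: float, hi: float, rate: float,
                   order: int = 4, axis: int = -1) -> np.ndarray:
    """Zero-phase Butterworth bandpass on a bare array."""
    sos = signal.butter(order, (lo, hi), btype="bandpass", fs=rate, output="sos")
    return signal.sosfiltfilt(sos, x, axis=axis)


# ---------------------------------------------------------------------------
# epoching and rejection
# ---------------------------------------------------------------------------


def epoch(rec: Recording, window: tuple) -> TrialSet:
    """Cut one trial per event over ``window = (tmin, tmax)`` seconds.

    Events whose window falls outside the recording are skipped with a
    log entry rather than raising.
    """
    tmin, tmax = window
    i0 = int(round(tmin * rec.rate))
    n_samp = int(round((tmax - tmin) * rec.rate))
    trials, conds, skipped = [], [], []
    for _, ev in rec.events.iterrows():
        start = int(ev["sample"]) + i0
        if start < 0 or start + n_samp > rec.n_samples:
            skipped.append(int(ev["sample"]))
            continue
        trials.append(rec.data[:, start:start + n_samp])
        conds.append(str(ev["condition"]))
    times = tmin + np.arange(n_samp) / rec.rate
    data = (np.stack(trials) if trials
            else np.empty((0, rec.n_channels, n_samp)))
    ts = TrialSet(data, times, conds, rec.rate, log=list(rec.log))
    ts.log.append(f"epoch [{tmin}, {tmax}] s; {len(trials)} trials"
                  + (f"; skipped out-of-bounds events at {skipped}" if skipped else ""))
    return ts


def reject_variance_outliers(ts: TrialSet, k: float = 3.0) -> TrialSet:
    """Flag trials whose variance exceeds mean + k standard deviations.

    The per-trial statistic is the mean over channels of the per-channel
    variance; the threshold is a single pass over the currently retained
    trials (no iteration).
    """
    idx = np.flatnonzero(ts.retained)
    if len(idx) < 2:
        raise ValueError("need at least 2 retained trials")
    v = ts.data[idx].var(axis=2).mean(axis=1)
    thresh = v.mean() + k * v.std()
    retained = ts.retained.copy()
    retained[idx] = v <= thresh
    out = TrialSet(ts.data, ts.times, ts.conditions, ts.rate, retained,
                   list(ts.log))
    out.log.append(f"variance rejection k={k}: removed "
                   f"{int(ts.retained.sum() - retained.sum())} trials")
    return out


# ---------------------------------------------------------------------------
# homogeneous field correction
# ---------------------------------------------------------------------------


def hfc_projector(sensors: SensorArray) -> np.ndarray:
    """Projector onto the complement of the homogeneous-field model.

    With M the channels x 3 matrix of sensor orientations, a spatially
    uniform field b produces channel data M b; the returned
    ``P = I - M (M^T M)^-1 M^T`` nulls exactly that subspace.
    """
    M = sensors.orientations
    if len(M) < 4:
        raise ValueError("need >= 4 channels for HFC")
    if np.linalg.matrix_rank(M, tol=1e-9) < 3:
        raise ValueError("channel orientations are coplanar; homogeneous "
                         "field model is unidentifiable")
    return np.eye(len(M)) - M @ np.linalg.pinv(M)


def homogeneous_field_correction(data, sensors: SensorArray):
    """Remove the spatially homogeneous field component from a Recording
    or TrialSet (channel count must match the sensor array)."""
    P = hfc_projector(sensors)
    if isinstance(data, Recording):
        if data.n_channels != sensors.n_channels:
            raise ValueError("channel count mismatch")
        return data.copy_with(P @ data.data, "homogeneous field correction")
    if isinstance(data, TrialSet):
        if data.data.shape[1] != sensors.n_channels:
            raise ValueError("channel count mismatch")
        out = TrialSet(np.einsum("ij,tjs->tis", P, data.data), data.times,
                       data.conditions, data.rate, data.retained.copy(),
                       list(data.log))
        out.log.append("homogeneous field correction")
        return out
    raise TypeError("data must be a Recording or TrialSet")


def regress_components(rec: Recording, components: np.ndarray | None) -> Recording:
    """Hook for external artifact time courses (e.g. ICA components
    selected elsewhere): least-squares regression of each supplied time
    course out of every channel. ``None`` is a no-op."""
    if components is None:
        return rec.copy_with(rec.data.copy(), "component regression: none supplied")
    comp = np.atleast_2d(np.asarray(components, float))
    if comp.shape[1] != rec.n_samples:
        raise ValueError("component length must match the recording")
    comp = comp - comp.mean(axis=1, keepdims=True)
    beta, *_ = np.linalg.lstsq(comp.T, rec.data.T, rcond=None)
    return rec.copy_with(rec.data - (comp.T @ beta).T,
                         f"regressed {comp.shape[0]} external components")
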