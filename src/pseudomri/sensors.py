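"""Triaxial OPM sensor-array container.

Each physical OPM contributes three channels measuring the magnetic
field along three mutually orthogonal unit orientations; channels carry
a parent-sensor id so triads can be regrouped after transforms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class SensorArray:
    """Per-channel positions (mm), unit orientations, labels, sensor ids."""

    positions: np.ndarray
    orientations: np.ndarray
    labels: list
    sensor_ids: np.ndarray

    def __post_init__(self):
        self.positions = np.asarray(self.positions, float).reshape(-1, 3)
        self.orientations = np.asarray(self.orientations, float).reshape(-1, 3)
        self.sensor_ids = np.asarray(self.sensor_ids, int).reshape(-1)
        self.labels = list(self.labels)
        n = len(self.positions)
        if not (len(self.orientations) == len(self.labels) == len(self.sensor_ids) == n):
            raise ValueError("channel fields must have equal length")
        norms = np.linalg.norm(self.orientations, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("channel orientations must be unit vectors")
        for sid in np.unique(self.sensor_ids):
            tri = self.orientations[self.sensor_ids == sid]
            if len(tri) == 3 and not np.allclose(tri @ tri.T, np.eye(3), atol=1e-6):
                raise ValueError(f"sensor {sid}: triad not orthonormal")

    @property
    def n_channels(self) -> int:
        return len(self.positions)

    @property
    def n_sensors(self) -> int:
        return len(np.unique(self.sensor_ids))

    def transformed(self, transform) -> "SensorArray":
        """Map positions through the transform and orientations through
        its rotation part (renormalised)."""
        return SensorArray(transform.apply(self.positions),
                           transform.apply_vectors(self.orientations),
                           self.labels, self.sensor_ids.copy())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "label": self.labels, "sensor": self.sensor_ids,
            "x": self.positions[:, 0], "y": self.positions[:, 1],
            "z": self.positions[:, 2],
            "ox": self.orientations[:, 0], "oy": self.orientations[:, 1],
            "oz": self.orientations[:, 2]})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SensorArray":
        df = pd.read_csv(path)
        return cls(df[["x", "y", "z"]].to_numpy(),
                   df[["ox", "oy", "oz"]].to_numpy(),
                   df["label"].tolist(), df["sensor"].to_numpy())
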