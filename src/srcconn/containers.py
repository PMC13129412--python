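"""Core data containers shared by all pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class HeadModel:
    """Toy analytic forward model linking a volumetric source grid to sensors.

    Sensors live on the upper unit hemisphere; the source grid is a regular
    cubic lattice clipped to a ball strictly inside the sensor sphere.  The
    leadfield has one row per voxel (fixed scalar source orientation), each
    row scaled to unit norm so that beamformer depth bias is the only
    remaining gain inhomogeneity.

    Attributes
    ----------
    sensor_positions : (N_s, 3) float array
        Sensor coordinates on the unit sphere (arbitrary length units).
    grid_positions : (N_v, 3) float array
        Voxel coordinates inside the source ball.
    grid_spacing : float
        Lattice constant, same units as the positions.
    leadfield : (N_v, N_s) float array
        Gain of each voxel at each sensor, rows unit-norm.
    """

    sensor_positions: np.ndarray
    grid_positions: np.ndarray
    grid_spacing: float
    leadfield: np.ndarray

    def __post_init__(self) -> None:
        self.sensor_positions = np.asarray(self.sensor_positions, dtype=float)
        self.grid_positions = np.asarray(self.grid_positions, dtype=float)
        self.leadfield = np.asarray(self.leadfield, dtype=float)
        if self.grid_spacing <= 0:
            raise ValueError("grid_spacing must be positive")
        sensor_r = np.linalg.norm(self.sensor_positions, axis=1).min()
        grid_r = np.linalg.norm(self.grid_positions, axis=1).max()
        if grid_r >= sensor_r:
            raise ValueError(
                "every grid position must lie strictly inside the sensor sphere "
                f"(max voxel radius {grid_r:.4f} >= min sensor radius {sensor_r:.4f})"
            )
        if np.any(np.all(self.leadfield == 0.0, axis=1)):
            raise ValueError("leadfield contains an all-zero row")
        d = np.linalg.norm(
            self.sensor_positions[:, None, :] - self.sensor_positions[None, :, :], axis=-1
        )
        np.fill_diagonal(d, np.inf)
        if d.min() == 0.0:
            raise ValueError("sensor positions must be pairwise distinct")

    @property
    def n_sensors(self) -> int:
        return self.sensor_positions.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.grid_positions.shape[0]


@dataclass
class SensorEpochs:
    """Epoched multichannel sensor data: trials x sensors x samples.

    Attributes
    ----------
    data : (n_trials, n_sensors, n_samples) float array
        Sensor voltages, nominally in microvolt.
    fs : float
        Sampling rate in Hz.
    t0 : float
        Time of sample 0 relative to stimulus onset, in seconds.
    condition : (n_trials,) array of str
        Per-trial condition label.
    sensor_positions : (n_sensors, 3) float array
    subject_id : str
    """

    data: np.ndarray
    fs: float
    t0: float
    condition: np.ndarray
    sensor_positions: np.ndarray
    subject_id: str = "unknown"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.condition = np.asarray(self.condition)
        self.sensor_positions = np.asarray(self.sensor_positions, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x sensors x samples")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("epoch data contains non-finite values")
        if len(self.condition) != self.data.shape[0]:
            raise ValueError("one condition label per trial required")
        if self.sensor_positions.shape[0] != self.data.shape[1]:
            raise ValueError("one sensor position per channel required")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_sensors(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds relative to stimulus onset."""
        return self.t0 + np.arange(self.n_samples) / self.fs

    def select_condition(self, label: str) -> "SensorEpochs":
        """Return a view-like copy restricted to trials of one condition."""
        mask = self.condition == label
        if not mask.any():
            raise ValueError(f"no trials with condition {label!r}")
        return SensorEpochs(
            data=self.data[mask],
            fs=self.fs,
            t0=self.t0,
            condition=self.condition[mask],
            sensor_positions=self.sensor_positions,
            subject_id=self.subject_id,
        )
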