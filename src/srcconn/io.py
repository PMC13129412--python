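"""File I/O: the canonical HDF5 epoch layout, delimited import and
JSON/CSV export of derived results.

HDF5 layout (one file per subject)::

    /epochs            float32, trials x sensors x samples
    /fs                scalar Hz
    /t0                scalar s
    /condition         string array, one label per trial
    /sensor_positions  N_s x 3
    /ground_truth/*    optional generative parameters (synthetic cohorts)
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .containers import SensorEpochs
from .synthetic import GroundTruth


class FormatError(ValueError):
    """Raised when an input file cannot be parsed under the named dialect."""


def save_epochs(
    path: str | Path,
    epochs: SensorEpochs,
    ground_truth: GroundTruth | None = None,
) -> None:
    """Write a SensorEpochs object (and optional ground truth) to HDF5."""
    with h5py.File(path, "w") as f:
        f.create_dataset("epochs", data=epochs.data.astype(np.float32))
        f.create_dataset("fs", data=float(epochs.fs))
        f.create_dataset("t0", data=float(epochs.t0))
        f.create_dataset(
            "condition",
            data=np.array([str(c) for c in epochs.condition], dtype="S"),
        )
        f.create_dataset("sensor_positions", data=epochs.sensor_positions)
        f.attrs["subject_id"] = epochs.subject_id
        if ground_truth is not None:
            g = f.create_group("ground_truth")
            g.create_dataset(
                "source_voxel_indices",
                data=np.asarray(ground_truth.source_voxel_indices, dtype=int),
            )
            g.create_dataset("linear_coupling", data=ground_truth.linear_coupling)
            g.create_dataset(
                "nonlinear_coupling", data=ground_truth.nonlinear_coupling
            )
            g.create_dataset("band", data=np.asarray(ground_truth.band))
            g.create_dataset("seed", data=int(ground_truth.seed))
            g.create_dataset("drive_amplitude", data=ground_truth.drive_amplitude)
            g.create_dataset("noise_std", data=ground_truth.noise_std)
            g.attrs["condition_effects"] = json.dumps(
                ground_truth.condition_effects, sort_keys=True
            )


def load_epochs(path: str | Path) -> SensorEpochs:
    """Read a SensorEpochs object from the canonical HDF5 layout."""
    with h5py.File(path, "r") as f:
        for key in ("epochs", "fs", "t0", "condition", "sensor_positions"):
            if key not in f:
                raise FormatError(f"{path}: missing dataset /{key}")
        return SensorEpochs(
            data=f["epochs"][()].astype(float),
            fs=float(f["fs"][()]),
            t0=float(f["t0"][()]),
            condition=np.array([c.decode() for c in f["condition"][()]]),
            sensor_positions=f["sensor_positions"][()],
            subject_id=str(f.attrs.get("subject_id", "unknown")),
        )


def load_ground_truth(path: str | Path) -> GroundTruth | None:
    """Read the ground-truth group from a cohort HDF5 file, if present."""
    with h5py.File(path, "r") as f:
        if "ground_truth" not in f:
            return None
        g = f["ground_truth"]
        return GroundTruth(
            source_voxel_indices=list(g["source_voxel_indices"][()]),
            linear_coupling=g["linear_coupling"][()],
            nonlinear_coupling=g["nonlinear_coupling"][()],
            band=tuple(g["band"][()]),
            condition_effects=json.loads(g.attrs["condition_effects"]),
            seed=int(g["seed"][()]),
            drive_amplitude=np.asarray(g["drive_amplitude"][()]),
            noise_std=float(g["noise_std"][()]),
        )


def read_delimited_epochs(
    path: str | Path,
    positions_path: str | Path | None = None,
    fs: float | None = None,
    t0: float = 0.0,
    subject_id: str = "unknown",
) -> SensorEpochs:
    """Read long-format delimited epochs.

    Expected columns (header row, comma- or tab-separated):
    ``trial, sensor, sample, value[, condition]``.  Sensor 3-D positions
    come from a side-car delimited table (columns x, y, z, one row per
    sensor in index order) because the long format cannot carry them.
    """
    import pandas as pd

    if positions_path is None:
        raise FormatError(
            f"{path}: delimited epochs need a side-car sensor-position table "
            "(columns x, y, z); pass positions_path"
        )
    if fs is None:
        raise FormatError(f"{path}: sampling rate fs must be supplied")
    try:
        df = pd.read_csv(path, sep=None, engine="python")
    except Exception as exc:  # pandas reports the offending line number
        raise FormatError(f"{path}: cannot parse delimited file: {exc}") from exc
    required = {"trial", "sensor", "sample", "value"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    for col in ("trial", "sensor", "sample", "value"):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
            raise FormatError(
                f"{path}: non-numeric {col!r} at line {line}"
            )
        df[col] = pd.to_numeric(df[col])

    trials = np.sort(df["trial"].unique())
    sensors = np.sort(df["sensor"].unique())
    samples = np.sort(df["sample"].unique())
    expected = len(trials) * len(sensors) * len(samples)
    if len(df) != expected:
        raise FormatError(
            f"{path}: inconsistent trial lengths — {len(df)} rows, expected "
            f"{expected} for a full trials x sensors x samples grid"
        )
    cube = (
        df.sort_values(["trial", "sensor", "sample"])["value"]
        .to_numpy()
        .reshape(len(trials), len(sensors), len(samples))
    )
    if "condition" in df.columns:
        labels = (
            df.drop_duplicates("trial").sort_values("trial")["condition"]
            .astype(str)
            .to_numpy()
        )
    else:
        labels = np.full(len(trials), "", dtype=object)

    pos = pd.read_csv(positions_path, sep=None, engine="python")
    if not {"x", "y", "z"} <= set(pos.columns):
        raise FormatError(
            f"{positions_path}: side-car table needs columns x, y, z"
        )
    positions = pos[["x", "y", "z"]].to_numpy(dtype=float)
    if positions.shape[0] != len(sensors):
        raise FormatError(
            f"{positions_path}: {positions.shape[0]} positions for "
            f"{len(sensors)} sensors"
        )
    return SensorEpochs(
        data=cube, fs=fs, t0=t0, condition=labels,
        sensor_positions=positions, subject_id=subject_id,
    )


def clusters_to_json(clusters, path: str | Path) -> None:
    """Export voxel clusters as JSON."""
    payload = [
        {
            "members": [int(v) for v in c.member_voxel_indices],
            "centroid": [float(x) for x in c.centroid],
            "kind": c.kind,
            "sign": c.sign,
            "label": c.label,
        }
        for c in clusters
    ]
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def source_map_to_table(source_map, hm, path: str | Path) -> None:
    """Export a source power map as a delimited table."""
    import pandas as pd

    pd.DataFrame(
        {
            "voxel": np.arange(hm.n_voxels),
            "x": hm.grid_positions[:, 0],
            "y": hm.grid_positions[:, 1],
            "z": hm.grid_positions[:, 2],
            "nai": source_map.nai,
            "condition": source_map.condition,
        }
    ).to_csv(path, index=False)
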