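"""Shared fixtures: small head models and ground-truth processes."""

import numpy as np
import pytest

from srcconn import build_head_model, simulate_source_dynamics, project_to_sensors
from srcconn.synthetic import GroundTruth, default_ground_truth


@pytest.fixture(scope="session")
def head_model():
    """60-sensor, 9^3-lattice toy head model."""
    return build_head_model(60, 9, 0.8, seed=1)


@pytest.fixture(scope="session")
def head_model_small():
    """Cheap 16-sensor model for connectivity-only tests."""
    return build_head_model(16, 9, 0.8, seed=1)


@pytest.fixture(scope="session")
def gt_alpha(head_model_small):
    """Two-source alpha-band ground truth, nonlinear coupling 1 -> 2."""
    return default_ground_truth(head_model_small, band=(8.0, 12.0))


@pytest.fixture(scope="session")
def gt_theta(head_model_small):
    """Two-source theta-band ground truth, nonlinear coupling 1 -> 2."""
    return default_ground_truth(head_model_small, band=(4.0, 7.0))


def make_uncoupled_gt(band=(8.0, 12.0), k=2):
    """Independent self-lag-only channels (null coupling)."""
    A = np.zeros((k, k, 2))
    for i in range(k):
        A[i, i, 0] = 0.5
        A[i, i, 1] = -0.2
    return GroundTruth(
        source_voxel_indices=list(range(k)),
        linear_coupling=A,
        nonlinear_coupling=np.zeros((k, k)),
        band=band,
        condition_effects={},
        drive_amplitude=1.0,
        noise_std=0.2,
    )


@pytest.fixture(scope="session")
def sine_epochs():
    """Pure 10-Hz sinusoid epochs on 4 sensors, amplitude 2 uV."""
    from srcconn.containers import SensorEpochs

    fs = 256.0
    t = np.arange(768) / fs
    data = np.tile(2.0 * np.sin(2 * np.pi * 10.0 * t), (3, 4, 1))
    pos = np.column_stack([np.arange(4), np.zeros(4), np.zeros(4)]).astype(float)
    return SensorEpochs(
        data=data, fs=fs, t0=-0.5, condition=np.array(["a"] * 3),
        sensor_positions=pos,
    )
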