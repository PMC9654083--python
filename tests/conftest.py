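"""Shared fixtures: short synthetic trials generated once per session."""

import numpy as np
import pytest

from gaitkf.erkf import NoiseConfig
from gaitkf.simulator import GaitSpec, generate_truth, synthesize_imu


@pytest.fixture(scope="session")
def truth10():
    """Noise-free forward-normal ground truth, 10 s."""
    return generate_truth(GaitSpec.preset("forward_normal", trial_duration=10.0))


@pytest.fixture(scope="session")
def imu10(truth10):
    """Noise-free synthesized IMU streams for the 10 s trial."""
    return synthesize_imu(truth10)


@pytest.fixture(scope="session")
def imu10_noisy(truth10):
    """Sensor-noise-corrupted streams for the 10 s trial (fixed seed)."""
    return synthesize_imu(truth10, noise=NoiseConfig(), seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_unit_quaternion(rng, n=None):
    q = rng.normal(size=(4,) if n is None else (n, 4))
    return q / np.linalg.norm(q, axis=-1, keepdims=True)
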