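import numpy as np
import pytest

from scigait import GaitProfile, NoiseModel, process_trial, simulate_trial


@pytest.fixture(scope="session")
def clean_trial():
    """60 s noise-free trial with default gait (stride 1.1 s / 1.2 m)."""
    profile = GaitProfile(trial_duration=60.0)
    left, right, truth = simulate_trial(profile, NoiseModel(0.0, 0.0, 0.0, seed=1))
    return profile, left, right, truth


@pytest.fixture(scope="session")
def clean_processed(clean_trial):
    profile, left, right, truth = clean_trial
    feature_set, side_params, sides = process_trial(left, right)
    return side_params, sides


@pytest.fixture(scope="session")
def noisy_trial():
    """Same gait with sensor noise (accel 0.1 m/s², gyro 0.05 rad/s)."""
    profile = GaitProfile(trial_duration=60.0)
    left, right, truth = simulate_trial(
        profile, NoiseModel(accel_noise_sd=0.1, gyro_noise_sd=0.05, seed=7))
    return profile, left, right, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
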