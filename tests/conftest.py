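import numpy as np
import pytest

from tactsparse import (
    GraspModel,
    JitterSpec,
    generate_dataset,
    generate_grasp,
    lowpass_denoise,
)

# A physically smaller model for unit tests where only structure matters:
# 128 frames x 16 x 16 grid keeps transforms and IO fast.
SMALL = GraspModel(
    grid_rows=16,
    grid_cols=16,
    n_active_sensors=140,
    sampling_rate=16.0,
    duration=8.0,
    onset_time=1.5,
    offset_time=6.5,
    peak_pressure=600.0,
    n_blobs=2,
    blob_width=1.5,
    noise_sd=2.0,
    seed=7,
)


@pytest.fixture(scope="session")
def model():
    """Study-condition grasp model (32x32 grid, 548 sensors, ~5 s grasp)."""
    return GraspModel()


@pytest.fixture(scope="session")
def small_model():
    return SMALL


@pytest.fixture(scope="session")
def recording(model):
    return generate_grasp(model)


@pytest.fixture(scope="session")
def denoised(recording):
    return lowpass_denoise(recording)


@pytest.fixture(scope="session")
def small_recording(small_model):
    return generate_grasp(small_model)


@pytest.fixture(scope="session")
def small_denoised(small_recording):
    return lowpass_denoise(small_recording)


@pytest.fixture(scope="session")
def small_dataset(small_model):
    recs = generate_dataset(small_model, 3, JitterSpec(onset_sd=0.2, amplitude_sd=0.05, center_sd=0.5))
    return [lowpass_denoise(r) for r in recs]


@pytest.fixture()
def rng():
    return np.random.default_rng(20240629)
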