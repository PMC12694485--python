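import numpy as np
import pytest
from hypothesis import settings

import emgspeller as es

settings.register_profile("repeatable", derandomize=True, deadline=None, database=None)
settings.load_profile("repeatable")


@pytest.fixture(scope="session")
def trial_script() -> es.GestureScript:
    """One command-recognition trial: five commands twice, 2 s rests."""
    return es.experiment1_script(1, 1)[0]


@pytest.fixture(scope="session")
def high_snr_recording(trial_script) -> es.EmgRecording:
    """High-SNR synthetic trial (burst RMS 100x the noise floor)."""
    params = es.BurstModelParams(
        baseline_noise_sd=15.0, burst_amplitude=1500.0, seed=42
    )
    return es.generate_recording(trial_script, params)


@pytest.fixture(scope="session")
def decoded_trial(high_snr_recording) -> es.DecodeResult:
    return es.decode_recording(high_snr_recording)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
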