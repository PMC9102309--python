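import numpy as np
import pytest

from wpdcca import SynthConfig, generate_paired


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def short_eeg_pair():
    """A small EEG pair (150 s at 256 Hz) for fast pipeline tests."""
    cfg = SynthConfig(modality="EEG", duration_s=150.0, fs=256.0,
                      artifact_interval_s=60.0,
                      artifact_duration_range_s=(8.0, 15.0), seed=7)
    return generate_paired(cfg)


@pytest.fixture(scope="session")
def short_fnirs_pair():
    """A small fNIRS pair (150 s at 25 Hz)."""
    cfg = SynthConfig(modality="fNIRS", duration_s=150.0,
                      artifact_interval_s=60.0,
                      artifact_duration_range_s=(8.0, 15.0), seed=7)
    return generate_paired(cfg)
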