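import numpy as np
import pytest

from ecgdenoise import EnsembleConfig, Signal, SynthConfig, synth_ecg


@pytest.fixture(scope="session")
def ecg() -> Signal:
    """One deterministic 10 s, 360 Hz synthetic ECG at 72 bpm."""
    return synth_ecg(SynthConfig(seed=42))


@pytest.fixture(scope="session")
def small_ensemble() -> EnsembleConfig:
    """Small ensemble for fast decompositions in unit tests."""
    return EnsembleConfig(ensemble_size=8, seed=0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
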