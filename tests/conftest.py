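import numpy as np
import pytest

from twinpcg import HeartSoundRecord, SynthesisConfig, synthesize_pcg


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def noise_record(rng):
    return HeartSoundRecord("noise", rng.standard_normal(10_000), 2000)


@pytest.fixture
def quiet_pcg():
    """A clean synthetic PCG: no murmur, no sensor noise."""
    cfg = SynthesisConfig(noise_sd=0.0, heart_rate_bpm=60.0, seed=1)
    return synthesize_pcg(cfg, "normal")


@pytest.fixture
def toy_separable():
    """6-point linearly separable 2-D set; +1 class near origin."""
    A = np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 0.0]])
    B = np.array([[3.0, 3.0], [3.0, 4.0], [4.0, 3.0]])
    X = np.vstack([A, B])
    y = np.array([1, 1, 1, -1, -1, -1])
    return X, y
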