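import numpy as np
import pytest

import gradpuff as gp


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def fse_recording():
    """A 5 s FSE-like synthetic recording with ground truth (low noise)."""
    cfg = gp.sequence_preset("FSE-like", "coronal", duration=5.0, noise_sd=0.01, seed=7)
    rec, truth = gp.generate_recording(cfg)
    return cfg, rec, truth


@pytest.fixture(scope="session")
def white_noise_2000():
    return np.random.default_rng(99).standard_normal(2000)
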