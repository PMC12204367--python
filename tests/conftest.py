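import numpy as np
import pytest
from hypothesis import settings

from abrkit import SynthConfig, generate_dataset

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_dataset():
    """Six subjects x 2 frequencies, noise-free: fast and fully predictable."""
    cfg = SynthConfig(n_subjects=6, frequencies_khz=(8.0, 16.0),
                      noise_sd_uv=0.0, seed=123)
    stacks, truth = generate_dataset(cfg)
    return cfg, stacks, truth


@pytest.fixture(scope="session")
def noisy_dataset():
    """Same layout with the default 0.2 uV recording noise."""
    cfg = SynthConfig(n_subjects=6, frequencies_khz=(8.0, 16.0), seed=123)
    stacks, truth = generate_dataset(cfg)
    return cfg, stacks, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
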