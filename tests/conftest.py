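import numpy as np
import pytest

from twix.synthetic import GeneratorConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A compact dataset shared by tests that only read from it."""
    cfg = GeneratorConfig(n_videos=6, samples_per_video=8, seed=42)
    return generate_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
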