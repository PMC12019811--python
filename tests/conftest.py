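import numpy as np
import pytest

from ntsvae import GeneratorConfig, generate_nts


@pytest.fixture(scope="session")
def small_truth():
    """A small generated NTS with default masking (shared, read-only)."""
    return generate_nts(GeneratorConfig(n_nodes=8, n_steps=30, seed=11))


@pytest.fixture(scope="session")
def small_bundle(small_truth):
    return small_truth.bundle


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
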