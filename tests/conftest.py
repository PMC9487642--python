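import numpy as np
import pytest

from trionet.trio_simulator import SimConfig, render_tensors, simulate_truth


@pytest.fixture(scope="session")
def small_sim():
    """A small clean trio cohort shared across tests."""
    config = SimConfig(n_sites=300, window=5, depth_rows=8, seed=11, denovo_rate=0.0)
    truth = simulate_truth(config)
    dataset = render_tensors(truth, config)
    return config, truth, dataset


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_distributions(rng, n, k=21):
    x = rng.gamma(1.0, size=(n, k))
    return x / x.sum(axis=1, keepdims=True)
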