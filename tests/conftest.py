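import numpy as np
import pytest

from epistasim.network import EpistasisNetwork


@pytest.fixture
def two_locus_net():
    """Two beneficial loci with a positive interaction."""
    return EpistasisNetwork(
        ["i", "j"], s=[0.1, 0.1], epsilon={("i", "j"): 0.05}
    )


@pytest.fixture
def neutral_net():
    """Six loci, no selection, no epistasis."""
    return EpistasisNetwork([f"L{k}" for k in range(6)], s=np.zeros(6))


def random_network(rng, n_loci, eps_scale=0.3, s_scale=0.2, density=1.0):
    """Small dense random network for oracle comparisons."""
    ids = [f"L{k}" for k in range(n_loci)]
    s = rng.uniform(-s_scale, s_scale, n_loci)
    eps = {}
    for a in range(n_loci):
        for b in range(a + 1, n_loci):
            if rng.random() < density:
                eps[(ids[a], ids[b])] = rng.uniform(-eps_scale, eps_scale)
    return EpistasisNetwork(ids, s=s, epsilon=eps)
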