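import networkx as nx
import numpy as np
import pytest

from scld import synthetic


@pytest.fixture(scope="session")
def default_config():
    return synthetic.SyntheticConfig(seed=1)


@pytest.fixture(scope="session")
def inputs(default_config):
    """One full set of synthetic pipeline inputs, shared across tests."""
    return synthetic.gen_all(default_config)


@pytest.fixture(scope="session")
def panel(inputs):
    return inputs.panel


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def planted_two_block_graph(n: int = 20, w_in: float = 0.8, w_out: float = 0.1):
    """Complete weighted graph with two planted blocks of n/2 nodes."""
    g = nx.Graph()
    half = n // 2
    names = [f"n{i:02d}" for i in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            w = w_in if (i < half) == (j < half) else w_out
            g.add_edge(names[i], names[j], weight=w)
    blocks = [set(names[:half]), set(names[half:])]
    return g, blocks


@pytest.fixture()
def two_block_graph():
    return planted_two_block_graph()
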