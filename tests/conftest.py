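import networkx as nx
import numpy as np
import pandas as pd
import pytest

from anchornet import simulate


@pytest.fixture(scope="session")
def chain_net():
    """Three-gene chain X -> Y -> Z with known weights."""
    return simulate.TrueNetwork(
        nodes=("X", "Y", "Z"),
        edges=(("X", "Y", 1.2), ("Y", "Z", -0.8)),
        noise_sd=1.0,
        roles={"X": "anchor", "Y": "other", "Z": "other"},
        tf_pairs=(("X", "Y"),),
    )


@pytest.fixture(scope="session")
def random_net():
    return simulate.generate_true_dag(20, 2.0, n_tfs=5, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_digraph(n_nodes: int, p_edge: float, seed: int) -> nx.DiGraph:
    """Random directed graph (cycles allowed) for path/cycle oracles."""
    r = np.random.default_rng(seed)
    g = nx.DiGraph()
    g.add_nodes_from(range(n_nodes))
    for i in range(n_nodes):
        for j in range(n_nodes):
            if i != j and r.random() < p_edge:
                g.add_edge(i, j)
    return g
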