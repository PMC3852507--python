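import sys
from pathlib import Path

import networkx as nx
import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from mran.simulate import make_truth, simulate_dataset


@pytest.fixture(scope="session")
def small_study():
    """A compact synthetic study shared by the slower integration tests."""
    truth = make_truth(rng_seed=7)
    return simulate_dataset(truth=truth, with_hairpins=False)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_graph(rng, n, p):
    """Seeded Erdos-Renyi graph with string node labels."""
    g = nx.Graph()
    nodes = [f"v{i}" for i in range(n)]
    g.add_nodes_from(nodes)
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                g.add_edge(nodes[i], nodes[j])
    return g
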