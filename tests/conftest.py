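import numpy as np
import pytest

from modlasso import build_network, make_benchmark


@pytest.fixture
def triangle_net():
    return build_network(
        [("A", "B"), ("B", "C"), ("A", "C")],
        {"A": "gene", "B": "gene", "C": "gene"},
    )


@pytest.fixture
def path_net():
    # A - B - C
    return build_network(
        [("A", "B"), ("B", "C")],
        {"A": "SNP", "B": "gene", "C": "protein"},
    )


@pytest.fixture
def two_edges_net():
    # two disjoint edges A-B, C-D
    return build_network(
        [("A", "B"), ("C", "D")],
        {"A": "gene", "B": "gene", "C": "gene", "D": "gene"},
    )


@pytest.fixture(scope="session")
def small_bench():
    return make_benchmark("small", seed=7)


@pytest.fixture(scope="session")
def default_bench():
    return make_benchmark("default", seed=7)


def random_graph(rng: np.random.Generator, p: int, edge_prob: float = 0.3):
    """Random connected-ish layered graph for property tests."""
    nodes = [f"n{i}" for i in range(p)]
    edges = []
    for i in range(p):
        for j in range(i + 1, p):
            if rng.random() < edge_prob:
                edges.append((nodes[i], nodes[j]))
    if not edges:  # guarantee m >= 1
        edges.append((nodes[0], nodes[-1]))
    layers = {n: ("SNP", "gene", "protein")[i % 3] for i, n in enumerate(nodes)}
    return build_network(edges, layers)
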