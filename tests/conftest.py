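import networkx as nx
import numpy as np
import pytest

from netheat import PPINetwork, SeedSet, column_normalize


@pytest.fixture
def two_node():
    """Single edge a-b; the analytically solvable diffusion case."""
    return PPINetwork.from_edges([("a", "b", 500)])


@pytest.fixture
def star():
    """Center c with leaves x (score 300) and y (score 900)."""
    return PPINetwork.from_edges([("c", "x", 300), ("c", "y", 900)])


@pytest.fixture
def path3():
    """Path a-b-c with equal scores."""
    return PPINetwork.from_edges([("a", "b", 400), ("b", "c", 400)])


def random_network(n: int, seed: int, p: float | None = None) -> PPINetwork:
    """ER random network with uniform integer scores; may be disconnected."""
    p = p if p is not None else min(1.0, 4.0 / n)
    rng = np.random.default_rng(seed)
    g = nx.gnp_random_graph(n, p, seed=seed)
    edges = [
        (f"n{a}", f"n{b}", int(rng.integers(150, 1000))) for a, b in g.edges()
    ]
    return PPINetwork.from_edges(edges, extra_nodes=[f"n{i}" for i in range(n)])


def random_seed_heat(network: PPINetwork, k: int, seed: int):
    """A random k-seed initial heat vector and its transition matrix."""
    from netheat import initial_heat

    tm = column_normalize(network)
    rng = np.random.default_rng(seed)
    members = list(rng.choice(np.array(tm.nodes, dtype=object), size=k, replace=False))
    return tm, initial_heat(SeedSet(members=members), tm.node_index)
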