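import networkx as nx
import numpy as np
import pandas as pd
import pytest

import fusemod as fm


@pytest.fixture
def small_cohort():
    """Planted two-subtype cohort at desk scale with its ground truth."""
    views, truth = fm.simulate_cohort(fm.CohortSpec(seed=7))
    return views, truth


@pytest.fixture
def two_triangles_bridge():
    """Two triangles joined by one bridge edge; optimal modularity 5/14."""
    return nx.Graph([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5), (2, 3)])


@pytest.fixture
def toy_distance():
    """Three patients on a line at coordinates 0, 1, 5."""
    X = pd.DataFrame([[0.0], [1.0], [5.0]], index=["a", "b", "c"])
    return fm.euclidean_distances(X)


def exhaustive_partitions(nodes):
    """All set partitions of ``nodes`` (oracle helper for tiny graphs)."""
    nodes = list(nodes)
    if not nodes:
        yield []
        return
    first, rest = nodes[0], nodes[1:]
    for p in exhaustive_partitions(rest):
        for i in range(len(p)):
            yield p[:i] + [p[i] | {first}] + p[i + 1 :]
        yield p + [{first}]


def random_small_graph(rng, n_min=4, n_max=7):
    n = int(rng.integers(n_min, n_max + 1))
    p = rng.uniform(0.3, 0.8)
    G = nx.Graph()
    G.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                G.add_edge(i, j)
    return G


@pytest.fixture
def random_affinity():
    """Factory for random symmetric affinity matrices with unit diagonal."""

    def make(n, rng):
        A = rng.uniform(0.05, 1.0, size=(n, n))
        W = (A + A.T) / 2
        np.fill_diagonal(W, 1.0)
        ids = [f"P{i:03d}" for i in range(n)]
        return pd.DataFrame(W, index=ids, columns=ids)

    return make
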