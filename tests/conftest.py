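import numpy as np
import pytest

from evoconn import AdjacencySpec, BrainGraph, CohortSpec, generate_feature_cohort


def graph_from_edges(n, edges, labels=None):
    labels = labels or [chr(ord("a") + i) for i in range(n)]
    a = np.zeros((n, n), dtype=int)
    idx = {lab: i for i, lab in enumerate(labels)}
    for u, v in edges:
        i, j = idx[u], idx[v]
        a[i, j] = a[j, i] = 1
    return BrainGraph(a, labels)


@pytest.fixture
def k3():
    return graph_from_edges(3, [("a", "b"), ("a", "c"), ("b", "c")])


@pytest.fixture
def p3():
    return graph_from_edges(3, [("a", "b"), ("b", "c")])


@pytest.fixture
def edgeless3():
    return graph_from_edges(3, [])


@pytest.fixture
def paw4():
    # triangle abc plus pendant d on c
    return graph_from_edges(4, [("a", "b"), ("a", "c"), ("b", "c"), ("c", "d")])


@pytest.fixture
def planted_table():
    """Small separable cohort: 2 informative among 12 features, effect 2."""
    spec = CohortSpec(n_group0=30, n_group1=30, n_features=12, n_informative=2, effect=2.0, seed=3)
    return generate_feature_cohort(spec)


def random_graph(rng, n, p=0.4):
    a = (rng.random((n, n)) < p).astype(int)
    a = np.triu(a, 1)
    a = a + a.T
    return BrainGraph(a, [f"n{i}" for i in range(n)])
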