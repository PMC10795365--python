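import networkx as nx
import numpy as np
import pytest

from lncpred.data_io import AssociationDataset, DiseaseOntology


@pytest.fixture
def chain_ontology():
    """d1 is the parent of d2."""
    g = nx.DiGraph()
    g.add_edge("d1", "d2")
    return DiseaseOntology(g, {"d1": "d1", "d2": "d2"})


@pytest.fixture
def sibling_ontology():
    """d2 and d3 are both children of d1."""
    g = nx.DiGraph()
    g.add_edge("d1", "d2")
    g.add_edge("d1", "d3")
    return DiseaseOntology(g, {"d1": "d1", "d2": "d2", "d3": "d3"})


@pytest.fixture
def diamond_ontology():
    """d4 has parents d2 and d3, which share the grandparent d1."""
    g = nx.DiGraph()
    g.add_edges_from([("d1", "d2"), ("d1", "d3"), ("d2", "d4"), ("d3", "d4")])
    return DiseaseOntology(g, {f"d{i}": f"d{i}" for i in range(1, 5)})


@pytest.fixture
def tiny_dataset():
    """2 lncRNAs x 2 diseases with an identity association matrix."""
    return AssociationDataset(["l1", "l2"], ["d1", "d2"], np.eye(2, dtype=int))


def random_dag(rng: np.random.Generator, n_nodes: int) -> nx.DiGraph:
    """Random DAG on n_nodes: edges only from lower to higher topological rank."""
    g = nx.DiGraph()
    g.add_nodes_from(range(n_nodes))
    for j in range(1, n_nodes):
        n_parents = int(rng.integers(1, min(j, 3) + 1))
        for p in rng.choice(j, size=n_parents, replace=False):
            g.add_edge(int(p), j)
    return g


def random_connected_graph(rng: np.random.Generator, n_nodes: int) -> np.ndarray:
    """Symmetric binary adjacency of a connected graph (spanning tree + extras)."""
    adj = np.zeros((n_nodes, n_nodes), dtype=int)
    for j in range(1, n_nodes):
        i = int(rng.integers(j))
        adj[i, j] = adj[j, i] = 1
    extra = rng.random((n_nodes, n_nodes)) < 0.15
    extra = np.triu(extra, 1)
    adj |= extra.astype(int) | extra.T.astype(int)
    np.fill_diagonal(adj, 0)
    return adj
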