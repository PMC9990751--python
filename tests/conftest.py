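import numpy as np
import pytest

from psne.graph_model import HetNet, NodeRef, WeightedGraph, disease, gene


def make_graph(edges, namespace="gene"):
    g = WeightedGraph()
    for e in edges:
        u, v = e[:2]
        w = e[2] if len(e) > 2 else 1.0
        g.add_edge(NodeRef(namespace, str(u)), NodeRef(namespace, str(v)), w)
    return g


@pytest.fixture
def triangle():
    return make_graph([("A", "B"), ("B", "C"), ("A", "C")])


@pytest.fixture
def path_abc():
    return make_graph([("A", "B"), ("B", "C")])


@pytest.fixture(scope="session")
def two_cliques():
    """Two 15-node cliques joined by a single bridge edge."""
    g = WeightedGraph()
    left = [gene(f"a{i:02d}") for i in range(15)]
    right = [gene(f"b{i:02d}") for i in range(15)]
    for side in (left, right):
        for i in range(15):
            for j in range(i + 1, 15):
                g.add_edge(side[i], side[j])
    g.add_edge(left[0], right[0])
    return g, left, right


@pytest.fixture(scope="session")
def clique_embedding(two_cliques):
    from psne.embedder import SGNSParams, train_embeddings
    from psne.walker import WalkParams, generate_walks

    g, left, right = two_cliques
    corpus = generate_walks(g, WalkParams(num_walks_per_node=30, walk_length=40, seed=11))
    emb = train_embeddings(corpus, SGNSParams(d=32, window=5, epochs=5, seed=11))
    return emb, left, right


@pytest.fixture(scope="session")
def tiny_hetnet():
    """Hand-built heterogeneous network: 3 diseases, 6 genes, 2 modules."""
    gg = make_graph(
        [("g1", "g2"), ("g2", "g3"), ("g1", "g3"),
         ("g4", "g5"), ("g5", "g6"), ("g4", "g6"), ("g3", "g4")]
    )
    dg = WeightedGraph()
    dg.add_edge(disease("d1"), gene("g1"))
    dg.add_edge(disease("d1"), gene("g2"))
    dg.add_edge(disease("d2"), gene("g4"))
    dg.add_edge(disease("d2"), gene("g5"))
    dg.add_edge(disease("d3"), gene("g2"))
    dg.add_edge(disease("d3"), gene("g5"))
    dd = WeightedGraph()
    dd.add_edge(disease("d1"), disease("d3"))
    dd.add_edge(disease("d2"), disease("d3"))
    return HetNet(dd, gg, dg)


def random_two_layer(rng, n_d=None, n_g=None, density=0.15):
    """Random non-negative two-layer network for propagation tests."""
    import scipy.sparse as sp

    from psne.reconstructor import TwoLayerNetwork

    n_d = n_d or int(rng.integers(3, 20))
    n_g = n_g or int(rng.integers(5, 60))
    diseases = [disease(f"d{i:03d}") for i in range(n_d)]
    genes = [gene(f"g{i:03d}") for i in range(n_g)]

    def sym_random(n):
        a = (rng.random((n, n)) < density) * rng.random((n, n))
        a = np.triu(a, 1)
        return a + a.T

    H_I = sym_random(n_d)
    H_N = sym_random(n_g)
    H_G = (rng.random((n_d, n_g)) < density) * rng.random((n_d, n_g))
    return TwoLayerNetwork(
        diseases, genes, sp.csr_matrix(H_I), sp.csr_matrix(H_N), sp.csr_matrix(H_G)
    )
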