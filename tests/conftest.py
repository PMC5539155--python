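import networkx as nx
import numpy as np
import pytest

from graphemd import CohortSpec, ExpressionProfile, GeneNetwork


def random_connected_network(rng: np.random.Generator, n: int, extra_edge_prob: float = 0.2) -> GeneNetwork:
    """Random connected simple graph: random labeled tree + extra edges."""
    tree = nx.random_labeled_tree(n, seed=int(rng.integers(2**31)))
    g = nx.Graph(tree)
    for i in range(n):
        for j in range(i + 1, n):
            if not g.has_edge(i, j) and rng.random() < extra_edge_prob:
                g.add_edge(i, j)
    width = len(str(n - 1))
    return GeneNetwork(nx.relabel_nodes(g, {i: f"N{i:0{width}d}" for i in g.nodes}))


def random_profile(rng: np.random.Generator, network: GeneNetwork, sample_id: str = "s") -> ExpressionProfile:
    """Log-normal expression, the positive-valued model the pipeline assumes."""
    return ExpressionProfile(sample_id, np.exp(rng.normal(0.0, 1.0, network.n_nodes)))


def random_prob(rng: np.random.Generator, n: int) -> np.ndarray:
    p = rng.random(n) + 1e-3
    return p / p.sum()


def delta(n: int, i: int) -> np.ndarray:
    d = np.zeros(n)
    d[i] = 1.0
    return d


@pytest.fixture
def path_network() -> GeneNetwork:
    """The 3-node path A-B-C used in the hand-worked examples."""
    return GeneNetwork.from_edges([("A", "B"), ("B", "C")])


@pytest.fixture
def path_profile() -> ExpressionProfile:
    return ExpressionProfile("hand", np.array([1.0, 2.0, 3.0]))


@pytest.fixture(scope="session")
def small_cohort_spec() -> CohortSpec:
    """A scaled-down cohort for fast pipeline tests (structure, not power)."""
    return CohortSpec(n_nodes=60, edges_per_node=2, group_sizes=(4, 4),
                      signature_frac=0.15, n_outliers=1, seed=7)
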