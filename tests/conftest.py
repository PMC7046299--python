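import networkx as nx
import numpy as np
import pandas as pd
import pytest

from wapscore import ExpressionDataset, GeneRanking, InteractionNetwork


def make_random_network(n_vertices: int, n_edges: int, seed: int) -> InteractionNetwork:
    g = nx.gnm_random_graph(n_vertices, n_edges, seed=seed)
    g = nx.relabel_nodes(g, {i: f"v{i:03d}" for i in g.nodes})
    return InteractionNetwork(g)


def make_random_ranking(genes, seed: int) -> GeneRanking:
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(list(genes)))
    return GeneRanking(tuple(order), -np.arange(len(order), dtype=float))


def make_dataset(matrix, genes=None, n_disease=None) -> ExpressionDataset:
    """Dataset from a genes x samples array; first n_disease columns are disease."""
    matrix = np.asarray(matrix, dtype=float)
    g, s = matrix.shape
    if genes is None:
        genes = [f"g{i:03d}" for i in range(g)]
    if n_disease is None:
        n_disease = s // 2
    cols = [f"d{i:02d}" for i in range(n_disease)] + [
        f"c{i:02d}" for i in range(s - n_disease)
    ]
    labels = {c: ("disease" if i < n_disease else "control") for i, c in enumerate(cols)}
    return ExpressionDataset(pd.DataFrame(matrix, index=genes, columns=cols), labels)


@pytest.fixture
def toy_network() -> InteractionNetwork:
    """5 genes: hub B, path tail, one isolated gene E."""
    return InteractionNetwork.from_edges(
        [("A", "B"), ("B", "C"), ("B", "D"), ("C", "D")], vertices=["E"]
    )


@pytest.fixture
def toy_ranking(toy_network) -> GeneRanking:
    return GeneRanking(("C", "A", "D", "B", "E"), -np.arange(5, dtype=float))


@pytest.fixture
def small_dataset() -> ExpressionDataset:
    rng = np.random.default_rng(7)
    return make_dataset(rng.standard_normal((20, 12)))
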