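import numpy as np
import pytest

from corelearn import (GeneGraph, GeneUniverse, SimulationConfig,
                       scale_features_robust, simulate_dataset)


def random_gene_graph(rng, n_nodes, n_relations, p_edge=0.3, directed=False):
    """Small random multi-network graph for layer oracles."""
    universe = GeneUniverse([f"g{i}" for i in range(n_nodes)])
    edge_sets, flags = {}, {}
    for r in range(n_relations):
        pairs = []
        for i in range(n_nodes):
            for j in range(n_nodes):
                if i != j and rng.random() < p_edge:
                    pairs.append((i, j))
        if not directed:
            # symmetrize
            sym = set()
            for i, j in pairs:
                sym.add((i, j))
                sym.add((j, i))
            pairs = sorted(sym)
        edge_sets[f"net{r}"] = np.asarray(pairs, dtype=np.int64).reshape(-1, 2)
        flags[f"net{r}"] = directed
    return GeneGraph(universe, edge_sets, flags)


@pytest.fixture(scope="session")
def toy_dataset():
    """Small planted-truth dataset shared by training/interpretation tests."""
    cfg = SimulationConfig(n_genes=60, core_fraction=0.2, effect_size=2.0,
                           label_frequency_slope=3.0, seed=11,
                           n_informative_features=3, n_noise_features=2)
    graph, feats, labels, truth = simulate_dataset(cfg)
    X = scale_features_robust(feats).values
    return graph, X, labels, truth


@pytest.fixture
def two_node_graph():
    u = GeneUniverse(["a", "b"])
    edges = np.array([[0, 1], [1, 0]])
    return GeneGraph(u, {"net": edges}, {"net": False})
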