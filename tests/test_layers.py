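"""Layer semantics against dense-matrix brute-force oracles."""

import numpy as np
import pytest

from corelearn import (ArchitectureSpec, GeneGraph, GeneUniverse,
                       build_graph_structure, layer_film, layer_gcn,
                       layer_rgcn, layer_tag, make_classifier,
                       normalize_instance)
from corelearn.autodiff import Tensor
from corelearn.nn import gcn_layer, instance_norm, tag_layer

from conftest import random_gene_graph


# ---------------------------------------------------------------------------
# Dense oracles (independent of the sparse implementation)
# ---------------------------------------------------------------------------

def dense_ahat(edges, n):
    A = np.zeros((n, n))
    for s, t in edges:
        A[t, s] += 1.0
    M = A + np.eye(n)
    d = M.sum(axis=1)  # in-degree of A+I
    inv = 1.0 / np.sqrt(d)
    return M * np.outer(inv, inv)


def dense_gcn(X, edges, W, n):
    return dense_ahat(edges, n) @ X @ W


def dense_tag(X, edges, Ws, n):
    Ahat = dense_ahat(edges, n)
    out = np.zeros((n, Ws[0].shape[1]))
    P = np.eye(n)
    for W in Ws:
        out += P @ X @ W
        P = Ahat @ P
    return out


def dense_rgcn(X, rel_edges, W_rel, W_root, n):
    out = X @ W_root
    for r, edges in enumerate(rel_edges):
        indeg = np.zeros(n)
        for s, t in edges:
            indeg[t] += 1
        for s, t in edges:
            out[t] += (X[s] @ W_rel[r]) / indeg[t]
    return out


def dense_film(X, rel_edges, W_rel, W_hyper, b_hyper, n):
    h = W_rel[0].shape[1]
    out = np.zeros((n, h))
    for r, edges in enumerate(rel_edges):
        gb = X @ W_hyper[r] + b_hyper[r]
        beta, gamma = gb[:, :h], gb[:, h:]
        for s, t in edges:
            out[t] += np.maximum(gamma[t] * (X[s] @ W_rel[r]) + beta[t], 0.0)
    return out


# ---------------------------------------------------------------------------
# GCN
# ---------------------------------------------------------------------------

class TestGCN:
    def test_isolated_node_identity_weights_keeps_row(self):
        u = GeneUniverse(["a", "b", "c"])
        g = GeneGraph(u, {"n": np.array([[0, 1], [1, 0]])}, {"n": False})
        X = np.arange(9.0).reshape(3, 3)
        out = layer_gcn(X, g, np.eye(3))
        np.testing.assert_allclose(out[2], X[2])  # degree-1 self loop only

    def test_two_node_edge_averages_features(self, two_node_graph):
        out = layer_gcn(np.eye(2), two_node_graph, np.eye(2))
        np.testing.assert_allclose(out, [[0.5, 0.5], [0.5, 0.5]])

    def test_empty_graph_reduces_to_dense_layer(self):
        u = GeneUniverse(["a", "b"])
        g = GeneGraph(u, {"n": np.empty((0, 2), dtype=int)}, {"n": False})
        X = np.array([[1.0, 2.0], [3.0, 4.0]])
        W = np.array([[1.0, 0.0], [1.0, 1.0]])
        np.testing.assert_allclose(layer_gcn(X, g, W), X @ W)


class TestTAG:
    def test_k_zero_is_a_dense_layer(self):
        u = GeneUniverse(["a", "b"])
        g = GeneGraph(u, {"n": np.array([[0, 1], [1, 0]])}, {"n": False})
        X = np.random.default_rng(0).normal(size=(2, 3))
        W = np.random.default_rng(1).normal(size=(3, 2))
        np.testing.assert_allclose(layer_tag(X, g, [W]), X @ W)

    def test_no_edges_identity_weights_give_k_plus_one_copies(self):
        u = GeneUniverse(["a", "b", "c"])
        g = GeneGraph(u, {"n": np.empty((0, 2), dtype=int)}, {"n": False})
        X = np.arange(6.0).reshape(3, 2)
        out = layer_tag(X, g, [np.eye(2)] * 4)  # K = 3
        np.testing.assert_allclose(out, 4 * X)


class TestRGCN:
    def make(self, rel_edges):
        u = GeneUniverse(["a", "b", "c"])
        sets = {f"n{r}": np.asarray(e, dtype=int).reshape(-1, 2)
                for r, e in enumerate(rel_edges)}
        return GeneGraph(u, sets, {k: True for k in sets})

    def test_no_neighbors_root_only(self):
        g = self.make([[]])
        X = np.arange(6.0).reshape(3, 2)
        W_root = np.array([[2.0, 0.0], [0.0, 2.0]])
        out = layer_rgcn(X, g, [np.eye(2)], W_root)
        np.testing.assert_allclose(out, X @ W_root)

    def test_single_neighbor_copies_neighbor(self):
        g = self.make([[(1, 0)]])
        X = np.arange(6.0).reshape(3, 2)
        out = layer_rgcn(X, g, [np.eye(2)], np.zeros((2, 2)))
        np.testing.assert_allclose(out[0], X[1])

    def test_two_neighbors_average(self):
        g = self.make([[(1, 0), (2, 0)]])
        X = np.arange(6.0).reshape(3, 2)
        out = layer_rgcn(X, g, [np.eye(2)], np.zeros((2, 2)))
        np.testing.assert_allclose(out[0], (X[1] + X[2]) / 2)


class TestFiLM:
    def setup_method(self):
        u = GeneUniverse(["a", "b"])
        self.g = GeneGraph(u, {"n": np.array([[1, 0]])}, {"n": True})
        self.X = np.array([[0.5, 1.0], [2.0, 3.0]])

    def hyper(self, beta, gamma):
        # zero weights, bias sets (beta, gamma) constants
        W = np.zeros((2, 4))
        b = np.concatenate([np.full(2, beta), np.full(2, gamma)])
        return [W], [b]

    def test_forced_zero_modulation_gives_zeros(self):
        Wh, bh = self.hyper(beta=0.0, gamma=0.0)
        out = layer_film(self.X, self.g, [np.eye(2)], Wh, bh)
        np.testing.assert_allclose(out, 0.0)

    def test_identity_modulation_passes_nonnegative_neighbor(self):
        Wh, bh = self.hyper(beta=0.0, gamma=1.0)
        out = layer_film(self.X, self.g, [np.eye(2)], Wh, bh)
        np.testing.assert_allclose(out[0], self.X[1])
        np.testing.assert_allclose(out[1], 0.0)  # no incoming edges

    def test_film_single_relation_reduces_to_unnormalized_sum(self):
        # gamma=1, beta=0: out[v] = sum_{u in N(v)} relu(W x_u)
        rng = np.random.default_rng(2)
        u = GeneUniverse([f"g{i}" for i in range(4)])
        edges = np.array([[1, 0], [2, 0], [3, 2]])
        g = GeneGraph(u, {"n": edges}, {"n": True})
        X = np.abs(rng.normal(size=(4, 2)))  # non-negative features
        W = np.abs(rng.normal(size=(2, 2)))
        Wh = [np.zeros((2, 4))]
        bh = [np.concatenate([np.zeros(2), np.ones(2)])]
        out = layer_film(X, g, [W], Wh, bh)
        expect = np.zeros((4, 2))
        for s, t in edges:
            expect[t] += X[s] @ W  # all terms non-negative: relu is identity
        np.testing.assert_allclose(out, expect)


class TestInstanceNorm:
    def test_moments(self):
        X = np.random.default_rng(3).normal(size=(50, 4)) * [1, 5, 0.7, 1]
        out = normalize_instance(X)
        np.testing.assert_allclose(out.mean(axis=0), 0, atol=1e-6)
        np.testing.assert_allclose(out.var(axis=0), 1, atol=1e-4)

    def test_constant_channel_guarded(self):
        X = np.c_[np.ones(10), np.arange(10.0)]
        out = normalize_instance(X)
        np.testing.assert_allclose(out[:, 0], 0.0)

    def test_single_node_rejected(self):
        with pytest.raises(ValueError):
            normalize_instance(np.ones((1, 3)))


# ---------------------------------------------------------------------------
# Brute-force oracle sweep and equivariance
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("kind", ["gcn", "tag", "rgcn", "film"])
def test_layers_match_dense_oracle_on_random_graphs(kind):
    """Sparse layer output equals the dense brute force on 25 seeded cases."""
    for seed in range(25):
        rng = np.random.default_rng(1000 + seed)
        n = int(rng.integers(2, 11))
        n_rel = int(rng.integers(1, 4)) if kind in ("rgcn", "film") else 1
        g = random_gene_graph(rng, n, n_rel, p_edge=0.4,
                              directed=kind in ("rgcn", "film"))
        p = int(rng.integers(1, 5))
        h = int(rng.integers(1, 4))
        X = rng.normal(size=(n, p))
        rel_edges = [list(map(tuple, g.edge_sets[f"net{r}"])) for r in range(n_rel)]
        if kind == "gcn":
            W = rng.normal(size=(p, h))
            got = layer_gcn(X, g, W)
            want = dense_gcn(X, rel_edges[0], W, n)
        elif kind == "tag":
            Ws = [rng.normal(size=(p, h)) for _ in range(4)]
            got = layer_tag(X, g, Ws)
            want = dense_tag(X, rel_edges[0], Ws, n)
        elif kind == "rgcn":
            W_rel = [rng.normal(size=(p, h)) for _ in range(n_rel)]
            W_root = rng.normal(size=(p, h))
            got = layer_rgcn(X, g, W_rel, W_root)
            want = dense_rgcn(X, rel_edges, W_rel, W_root, n)
        else:
            W_rel = [rng.normal(size=(p, h)) for _ in range(n_rel)]
            W_h = [rng.normal(size=(p, 2 * h)) for _ in range(n_rel)]
            b_h = [rng.normal(size=2 * h) for _ in range(n_rel)]
            got = layer_film(X, g, W_rel, W_h, b_h)
            want = dense_film(X, rel_edges, W_rel, W_h, b_h, n)
        np.testing.assert_allclose(got, want, atol=1e-5)


@pytest.mark.parametrize("kind", ["gcn", "tag"])
def test_permutation_equivariance(kind):
    rng = np.random.default_rng(7)
    n = 8
    g = random_gene_graph(rng, n, 1, p_edge=0.4)
    X = rng.normal(size=(n, 3))
    W = rng.normal(size=(3, 3))
    perm = rng.permutation(n)
    edges = g.edge_sets["net0"]
    g_perm = GeneGraph(GeneUniverse([f"g{i}" for i in range(n)]),
                       {"net0": np.c_[perm[edges[:, 0]], perm[edges[:, 1]]]},
                       {"net0": False})
    if kind == "gcn":
        base = layer_gcn(X, g, W)
        permuted = layer_gcn(X[np.argsort(perm)], g_perm, W)
    else:
        base = layer_tag(X, g, [W, W])
        permuted = layer_tag(X[np.argsort(perm)], g_perm, [W, W])
    np.testing.assert_allclose(permuted[perm], base, atol=1e-10)


# ---------------------------------------------------------------------------
# Full classifier forwards
# ---------------------------------------------------------------------------

class TestForwardClassifier:
    def test_zero_weights_score_half_everywhere(self, toy_dataset):
        graph, X, _, _ = toy_dataset
        for name in ("mlp", "gcn", "rgcn", "film", "linkx"):
            model = make_classifier(name, X.shape[1], graph, seed=0)
            model.zero_weights()
            np.testing.assert_allclose(model.scores(X), 0.5, atol=1e-12)

    def test_mlp_ignores_graph(self, toy_dataset):
        graph, X, _, _ = toy_dataset
        model = make_classifier("mlp", X.shape[1], graph, seed=1)
        s1 = model.scores(X)
        shuffled = GeneGraph(
            graph.universe,
            {k: v[::-1].copy() for k, v in graph.edge_sets.items()},
            dict(graph.directed_flags))
        model2 = make_classifier("mlp", X.shape[1], shuffled, seed=1)
        np.testing.assert_array_equal(s1, model2.scores(X))

    def test_gcn_forward_equals_hand_composed_chain(self, two_node_graph):
        spec = ArchitectureSpec(mp_kind="gcn", pre_layers=1, post_layers=0,
                                hidden_dim=3, mp_layers=1)
        model = make_classifier("gcn", 2, two_node_graph, spec=spec, seed=5)
        X = np.array([[1.0, -0.5], [0.3, 2.0]])
        got = model.scores(X)
        # hand-compose: pre dense+ELU -> gcn -> ELU -> instance norm -> head
        gs = build_graph_structure(two_node_graph, network="net")
        W0, b0 = model.pre[0]
        H = Tensor(X) @ W0 + b0
        H = H.elu()
        H = gcn_layer(H, gs, model.mp[0]["W"])
        H = instance_norm(H.elu())
        Wh, bh = model.head
        want = (H @ Wh + bh).sigmoid().reshape(-1).data
        np.testing.assert_allclose(got, want, atol=1e-12)

    def test_linkx_l1_penalty_arithmetic(self, toy_dataset):
        graph, X, _, _ = toy_dataset
        model = make_classifier("linkx", X.shape[1], graph, seed=0)
        pen = model.l1_penalty()
        want = 1e-2 * np.abs(model.A_layers[0][0].data).sum()
        np.testing.assert_allclose(float(pen.data), want, rtol=1e-12)
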