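"""Base classifiers: pre/message-passing/post architectures and embeddings.

Every classifier shares the same three-block design: a pre-message-passing
MLP projects the p input features to the hidden dimension, a stack of graph
message-passing layers (GCN, TAG, RGCN or FiLM — each followed by an ELU and
instance normalization) mixes information over the typed gene networks, and a
post-message-passing MLP maps to a single sigmoid output per gene.  Setting
the message-passing kind to ``none`` yields a plain MLP that ignores the
graph.  LINKX is the exception: it trains separate MLPs on adjacency rows and
on features and joins their latents.

All layers accept an optional per-edge weight vector that scales messages
multiplicatively.  A weight of 1 leaves message passing unchanged and a
weight of 0 removes the edge, which is what makes integrated-gradients edge
attribution well-defined for every classifier kind.

Spectral conventions: GCN and TAG use the renormalized propagation matrix
``Ahat = D^{-1/2} (A + I) D^{-1/2}`` with D the degree matrix of A + I, so
isolated nodes are convolved with themselves.  RGCN mean-normalizes each
relation's neighborhood; FiLM sums unnormalized messages modulated by a
per-relation, per-receiver (gamma, beta) pair from a one-layer hypernetwork.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, concat_cols
from .data import GeneGraph

logger = logging.getLogger("corelearn")

INSTANCE_NORM_EPS = 1e-5


@dataclass(frozen=True)
class ArchitectureSpec:
    """Hyperparameters of the pre / message-passing / post architecture."""

    mp_kind: str = "none"  # none | gcn | tag | rgcn | film
    pre_layers: int = 2
    post_layers: int = 2
    hidden_dim: int = 50
    mp_layers: int = 2
    tag_hops: int = 3
    network: str | None = None  # restrict single-relation layers to one network
    use_embedding: bool = False  # concatenate a node-embedding table to X

    def __post_init__(self):
        if self.hidden_dim <= 0:
            raise ValueError("hidden_dim must be positive")
        if self.tag_hops < 0:
            raise ValueError("tag_hops must be >= 0")
        if self.mp_kind not in {"none", "gcn", "tag", "rgcn", "film"}:
            raise ValueError(f"unknown mp_kind {self.mp_kind!r}")


# ---------------------------------------------------------------------------
# Graph preprocessing
# ---------------------------------------------------------------------------

@dataclass
class GraphStructure:
    """Edge arrays and normalization constants precomputed from a GeneGraph."""

    n_nodes: int
    # per relation: (src, dst) arrays and slices into the global edge vector
    rel_src: list[np.ndarray] = field(default_factory=list)
    rel_dst: list[np.ndarray] = field(default_factory=list)
    rel_slices: list[tuple[int, int]] = field(default_factory=list)
    rel_names: list[str] = field(default_factory=list)
    # merged single-relation view
    src: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    dst: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    gcn_coeff: np.ndarray = field(default_factory=lambda: np.empty(0))
    gcn_self_coeff: np.ndarray = field(default_factory=lambda: np.empty(0))
    rgcn_norm: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n_edges(self) -> int:
        return len(self.src)

    @property
    def n_relations(self) -> int:
        return len(self.rel_src)


def build_graph_structure(graph: GeneGraph, network: str | None = None) -> GraphStructure:
    """Precompute edge arrays and GCN/RGCN normalization constants.

    ``network`` restricts to one named edge set (for single-relation layers);
    otherwise all networks are kept as typed relations and the merged union is
    used by single-relation layers and the embedding.
    """
    names = [network] if network is not None else graph.network_names
    gs = GraphStructure(n_nodes=len(graph.universe))
    offset = 0
    all_src, all_dst = [], []
    for name in names:
        edges = graph.edge_sets[name]
        s = edges[:, 0].astype(np.int64)
        d = edges[:, 1].astype(np.int64)
        gs.rel_src.append(s)
        gs.rel_dst.append(d)
        gs.rel_slices.append((offset, offset + len(s)))
        gs.rel_names.append(name)
        offset += len(s)
        all_src.append(s)
        all_dst.append(d)
    gs.src = np.concatenate(all_src) if all_src else np.empty(0, dtype=np.int64)
    gs.dst = np.concatenate(all_dst) if all_dst else np.empty(0, dtype=np.int64)

    n = gs.n_nodes
    # GCN/TAG: degrees of A + I counted at the receiving end
    deg = np.ones(n)  # self-loop
    np.add.at(deg, gs.dst, 1.0)
    inv_sqrt = 1.0 / np.sqrt(deg)
    gs.gcn_coeff = inv_sqrt[gs.src] * inv_sqrt[gs.dst]
    gs.gcn_self_coeff = inv_sqrt * inv_sqrt
    # RGCN: 1 / |N_r(v)| per edge, by relation and receiver
    norms = np.empty(gs.n_edges)
    for (a, b), d_arr in zip(gs.rel_slices, gs.rel_dst):
        cnt = np.zeros(n)
        np.add.at(cnt, d_arr, 1.0)
        norms[a:b] = 1.0 / cnt[d_arr] if len(d_arr) else 1.0
    gs.rgcn_norm = norms
    return gs


# ---------------------------------------------------------------------------
# Message-passing layer forwards (operate on Tensors)
# ---------------------------------------------------------------------------

def _edge_w(weights: Tensor | None, a: int, b: int) -> Tensor | None:
    """Slice the global edge-weight vector to one relation's edges."""
    if weights is None:
        return None
    return weights.reshape(-1, 1).gather_rows(np.arange(a, b))


def gcn_propagate(X: Tensor, gs: GraphStructure, weights: Tensor | None = None) -> Tensor:
    """One application of ``Ahat`` (with self-loops) to X, messages scaled by weights."""
    n = gs.n_nodes
    self_part = X * Tensor(gs.gcn_self_coeff[:, None])
    if gs.n_edges == 0:
        return self_part
    msgs = X.gather_rows(gs.src) * Tensor(gs.gcn_coeff[:, None])
    w = _edge_w(weights, 0, gs.n_edges)
    if w is not None:
        msgs = msgs * w
    return msgs.segment_sum(gs.dst, n) + self_part


def gcn_layer(X: Tensor, gs: GraphStructure, W: Tensor,
              weights: Tensor | None = None) -> Tensor:
    """GCN: ``Ahat X W``."""
    return gcn_propagate(X, gs, weights) @ W


def tag_layer(X: Tensor, gs: GraphStructure, Ws: list[Tensor],
              weights: Tensor | None = None) -> Tensor:
    """TAG: ``sum_{k=0..K} Ahat^k X W_k``; the k=0 term is the skip connection."""
    out = X @ Ws[0]
    H = X
    for k in range(1, len(Ws)):
        H = gcn_propagate(H, gs, weights)
        out = out + H @ Ws[k]
    return out


def rgcn_layer(X: Tensor, gs: GraphStructure, W_rel: list[Tensor], W_root: Tensor,
               weights: Tensor | None = None) -> Tensor:
    """RGCN: root transform plus mean-normalized per-relation neighborhoods."""
    out = X @ W_root
    for r in range(gs.n_relations):
        a, b = gs.rel_slices[r]
        if b == a:
            continue
        src, dst = gs.rel_src[r], gs.rel_dst[r]
        msgs = (X.gather_rows(src) @ W_rel[r]) * Tensor(gs.rgcn_norm[a:b, None])
        w = _edge_w(weights, a, b)
        if w is not None:
            msgs = msgs * w
        out = out + msgs.segment_sum(dst, gs.n_nodes)
    return out


def film_layer(X: Tensor, gs: GraphStructure, W_rel: list[Tensor],
               W_hyper: list[Tensor], b_hyper: list[Tensor],
               weights: Tensor | None = None) -> Tensor:
    """FiLM: unnormalized sum of receiver-modulated, rectified messages.

    Per relation the hypernetwork ``g`` is a single dense layer producing the
    receiver-conditioned offset beta and coefficient gamma:
    ``(beta_v, gamma_v) = x_v W_{g,r} + b_{g,r}``.  The message from u to v is
    ``relu(gamma_v * (W_r x_u) + beta_v)``, scaled by the edge weight.
    """
    d_out = W_rel[0].shape[1]
    out: Tensor | None = None
    for r in range(gs.n_relations):
        a, b = gs.rel_slices[r]
        if b == a:
            continue
        src, dst = gs.rel_src[r], gs.rel_dst[r]
        gb = X @ W_hyper[r] + b_hyper[r]
        beta = gb.slice_cols(0, d_out).gather_rows(dst)
        gamma = gb.slice_cols(d_out, 2 * d_out).gather_rows(dst)
        msgs = (gamma * (X.gather_rows(src) @ W_rel[r]) + beta).relu()
        w = _edge_w(weights, a, b)
        if w is not None:
            msgs = msgs * w
        agg = msgs.segment_sum(dst, gs.n_nodes)
        out = agg if out is None else out + agg
    if out is None:
        out = Tensor(np.zeros((gs.n_nodes, d_out)))
    return out


def instance_norm(X: Tensor, eps: float = INSTANCE_NORM_EPS) -> Tensor:
    """Center and scale each feature channel across nodes (no learned affine)."""
    if X.shape[0] < 2:
        raise ValueError("instance normalization needs at least 2 nodes")
    mu = X.mean(axis=0, keepdims=True)
    centered = X - mu
    var = (centered * centered).mean(axis=0, keepdims=True)
    return centered * ((var + eps) ** -0.5)


# ---------------------------------------------------------------------------
# Functional layer API on plain arrays (spec surface; used by the oracles)
# ---------------------------------------------------------------------------

def layer_gcn(X: np.ndarray, graph: GeneGraph, W: np.ndarray,
              network: str | None = None) -> np.ndarray:
    gs = build_graph_structure(graph, network=network or _single_network(graph))
    return gcn_layer(Tensor(X), gs, Tensor(W)).data


def layer_tag(X: np.ndarray, graph: GeneGraph, Ws: list[np.ndarray],
              network: str | None = None) -> np.ndarray:
    gs = build_graph_structure(graph, network=network or _single_network(graph))
    return tag_layer(Tensor(X), gs, [Tensor(W) for W in Ws]).data


def layer_rgcn(X: np.ndarray, graph: GeneGraph, W_rel: list[np.ndarray],
               W_root: np.ndarray) -> np.ndarray:
    gs = build_graph_structure(graph)
    return rgcn_layer(Tensor(X), gs, [Tensor(W) for W in W_rel], Tensor(W_root)).data


def layer_film(X: np.ndarray, graph: GeneGraph, W_rel: list[np.ndarray],
               W_hyper: list[np.ndarray], b_hyper: list[np.ndarray]) -> np.ndarray:
    gs = build_graph_structure(graph)
    return film_layer(Tensor(X), gs, [Tensor(w) for w in W_rel],
                      [Tensor(w) for w in W_hyper], [Tensor(bv) for bv in b_hyper]).data


def normalize_instance(X: np.ndarray) -> np.ndarray:
    return instance_norm(Tensor(X)).data


def _single_network(graph: GeneGraph) -> str | None:
    names = graph.network_names
    return names[0] if len(names) == 1 else None


# ---------------------------------------------------------------------------
# Classifiers
# ---------------------------------------------------------------------------

def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class Classifier:
    """The pre / message-passing / post architecture with a sigmoid head."""

    def __init__(self, spec: ArchitectureSpec, in_dim: int, gs: GraphStructure,
                 seed: int = 0):
        self.spec = spec
        self.gs = gs
        rng = np.random.default_rng(seed)
        h = spec.hidden_dim
        self.params: list[Tensor] = []

        def dense(fi, fo):
            W = Tensor(_glorot(rng, fi, fo), requires_grad=True)
            b = Tensor(np.zeros(fo), requires_grad=True)
            self.params += [W, b]
            return W, b

        self.pre = []
        d = in_dim
        for _ in range(spec.pre_layers):
            self.pre.append(dense(d, h))
            d = h
        self.mp: list[dict] = []
        if spec.mp_kind != "none":
            n_rel = max(gs.n_relations, 1)
            for _ in range(spec.mp_layers):
                layer: dict = {"kind": spec.mp_kind}
                if spec.mp_kind == "gcn":
                    layer["W"] = Tensor(_glorot(rng, h, h), requires_grad=True)
                    self.params.append(layer["W"])
                elif spec.mp_kind == "tag":
                    layer["Ws"] = [Tensor(_glorot(rng, h, h), requires_grad=True)
                                   for _ in range(spec.tag_hops + 1)]
                    self.params += layer["Ws"]
                elif spec.mp_kind == "rgcn":
                    layer["W_root"] = Tensor(_glorot(rng, h, h), requires_grad=True)
                    layer["W_rel"] = [Tensor(_glorot(rng, h, h), requires_grad=True)
                                      for _ in range(n_rel)]
                    self.params += [layer["W_root"], *layer["W_rel"]]
                elif spec.mp_kind == "film":
                    layer["W_rel"] = [Tensor(_glorot(rng, h, h), requires_grad=True)
                                      for _ in range(n_rel)]
                    layer["W_hyper"] = [
                        Tensor(_glorot(rng, h, 2 * h) * 0.1, requires_grad=True)
                        for _ in range(n_rel)
                    ]
                    # bias starts at beta=0, gamma=1 so messages pass at init
                    layer["b_hyper"] = [
                        Tensor(np.concatenate([np.zeros(h), np.ones(h)]),
                               requires_grad=True)
                        for _ in range(n_rel)
                    ]
                    self.params += layer["W_rel"] + layer["W_hyper"] + layer["b_hyper"]
                self.mp.append(layer)
        self.post = []
        for _ in range(spec.post_layers):
            self.post.append(dense(h, h))
        self.head = dense(h, 1)

    @property
    def uses_graph(self) -> bool:
        return self.spec.mp_kind != "none"

    def forward(self, X: Tensor, edge_weights: Tensor | None = None) -> Tensor:
        """Per-gene score in (0, 1)."""
        H = X
        for W, b in self.pre:
            H = (H @ W + b).elu()
        for layer in self.mp:
            kind = layer["kind"]
            if kind == "gcn":
                H = gcn_layer(H, self.gs, layer["W"], edge_weights)
            elif kind == "tag":
                H = tag_layer(H, self.gs, layer["Ws"], edge_weights)
            elif kind == "rgcn":
                H = rgcn_layer(H, self.gs, layer["W_rel"], layer["W_root"], edge_weights)
            elif kind == "film":
                H = film_layer(H, self.gs, layer["W_rel"], layer["W_hyper"],
                               layer["b_hyper"], edge_weights)
            H = instance_norm(H.elu())
        for W, b in self.post:
            H = (H @ W + b).elu()
        W, b = self.head
        return (H @ W + b).sigmoid().reshape(-1)

    def scores(self, X: np.ndarray, edge_weights: np.ndarray | None = None) -> np.ndarray:
        w = Tensor(edge_weights) if edge_weights is not None else None
        return self.forward(Tensor(X), w).data

    def l1_penalty(self) -> Tensor | None:
        return None

    def get_weights(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.params]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.params, weights):
            p.data = w.copy()

    def zero_weights(self) -> None:
        for p in self.params:
            p.data = np.zeros_like(p.data)


class LinkxClassifier:
    """LINKX: separate MLPs on adjacency rows and features, joined by a third.

    The A-branch consumes each gene's dense adjacency row of the merged
    multi-network graph; its first weight matrix carries an L1 penalty
    (``l1_alpha``, default 1e-2) added to the training loss to curb
    overfitting of the n x h input layer.
    """

    def __init__(self, spec: ArchitectureSpec, in_dim: int, gs: GraphStructure,
                 seed: int = 0, l1_alpha: float = 1e-2):
        self.spec = spec
        self.gs = gs
        self.l1_alpha = l1_alpha
        rng = np.random.default_rng(seed)
        h = spec.hidden_dim
        n = gs.n_nodes
        self.params: list[Tensor] = []

        def dense(fi, fo, scale=1.0):
            W = Tensor(_glorot(rng, fi, fo) * scale, requires_grad=True)
            b = Tensor(np.zeros(fo), requires_grad=True)
            self.params += [W, b]
            return W, b

        self.A_layers = [dense(n, h), dense(h, h)]
        self.X_layers = [dense(in_dim, h), dense(h, h)]
        self.f_layers = [dense(2 * h, h)]
        self.head = dense(h, 1)

    def _adjacency(self, edge_weights: Tensor | None) -> Tensor:
        n = self.gs.n_nodes
        flat_idx = self.gs.src * n + self.gs.dst
        if edge_weights is None:
            A = np.zeros(n * n)
            np.add.at(A, flat_idx, 1.0)
            return Tensor(A.reshape(n, n))
        return edge_weights.reshape(-1, 1).segment_sum(flat_idx, n * n).reshape(n, n)

    def forward(self, X: Tensor, edge_weights: Tensor | None = None) -> Tensor:
        A = self._adjacency(edge_weights)
        HA = A
        for W, b in self.A_layers:
            HA = (HA @ W + b).elu()
        HX = X
        for W, b in self.X_layers:
            HX = (HX @ W + b).elu()
        H = concat_cols([HA, HX])
        for W, b in self.f_layers:
            H = (H @ W + b).elu()
        W, b = self.head
        return (H @ W + b).sigmoid().reshape(-1)

    def scores(self, X: np.ndarray, edge_weights: np.ndarray | None = None) -> np.ndarray:
        w = Tensor(edge_weights) if edge_weights is not None else None
        return self.forward(Tensor(X), w).data

    def l1_penalty(self) -> Tensor:
        W0 = self.A_layers[0][0]
        return W0.abs().sum() * self.l1_alpha

    uses_graph = True
    get_weights = Classifier.get_weights
    set_weights = Classifier.set_weights
    zero_weights = Classifier.zero_weights


# ---------------------------------------------------------------------------
# Registry
# ---------------------------------------------------------------------------

CLASSIFIER_REGISTRY = {"mlp", "gcn", "tag", "rgcn", "film", "n2v+mlp", "linkx"}


def make_classifier(name: str, in_dim: int, graph: GeneGraph,
                    spec: ArchitectureSpec | None = None, seed: int = 0,
                    embedding: np.ndarray | None = None):
    """Build a classifier by registry name.

    For ``n2v+mlp`` the caller passes the embedding table; the input features
    are the concatenation of X and the embedding rows, handled by
    :func:`classifier_inputs`.
    """
    if name not in CLASSIFIER_REGISTRY:
        raise KeyError(f"unknown classifier {name!r}; choose from {sorted(CLASSIFIER_REGISTRY)}")
    mp_map = {"mlp": "none", "n2v+mlp": "none", "gcn": "gcn", "tag": "tag",
              "rgcn": "rgcn", "film": "film"}
    if spec is None:
        spec = ArchitectureSpec(mp_kind=mp_map.get(name, "none"))
    elif name in mp_map and spec.mp_kind != mp_map[name]:
        spec = ArchitectureSpec(**{**spec.__dict__, "mp_kind": mp_map[name]})
    if name == "n2v+mlp":
        if embedding is None:
            raise ValueError("n2v+mlp requires an embedding table")
        in_dim = in_dim + embedding.shape[1]
    network = spec.network if spec.network else (
        _single_network(graph) if name in {"gcn", "tag"} else None)
    gs = build_graph_structure(graph, network=network)
    if name == "linkx":
        return LinkxClassifier(spec, in_dim, gs, seed=seed)
    return Classifier(spec, in_dim, gs, seed=seed)


def classifier_inputs(name: str, X: np.ndarray,
                      embedding: np.ndarray | None = None) -> np.ndarray:
    """Assemble the model input matrix (concatenates the embedding for n2v+mlp)."""
    if name == "n2v+mlp":
        if embedding is None:
            raise ValueError("n2v+mlp requires an embedding table")
        return np.hstack([X, embedding])
    return X


# ---------------------------------------------------------------------------
# Random-walk network embedding (skip-gram with negative sampling)
# ---------------------------------------------------------------------------

def embed_networks_randomwalk(
    graph: GeneGraph,
    d_emb: int = 100,
    walk_length: int = 100,
    context: int = 5,
    epochs: int = 500,
    walks_per_node: int = 10,
    n_negatives: int = 5,
    lr: float = 0.025,
    seed: int = 0,
) -> np.ndarray:
    """Unsupervised node embedding from unbiased random walks on the union graph.

    All networks are merged (edge types dropped) since the embedding is
    type-unaware.  Walks are unbiased (return and in-out parameters 1) and
    follow stored edge directions; a skip-gram model with negative sampling is
    trained on (center, context) pairs within the given window.  Nodes that
    never occur in a walk — in particular isolated nodes — receive zero
    vectors.  Deterministic under seed.
    """
    n = len(graph.universe)
    edges = graph.merged_edges()
    if len(edges) == 0:
        warnings.warn("embedding requested on a graph with no edges; returning zeros")
        return np.zeros((n, d_emb))
    rng = np.random.default_rng(seed)

    # adjacency in CSR-ish form
    order = np.argsort(edges[:, 0], kind="stable")
    src_sorted = edges[order, 0]
    dst_sorted = edges[order, 1]
    starts = np.searchsorted(src_sorted, np.arange(n + 1))

    # random walks
    walks = []
    for _ in range(walks_per_node):
        frontier = np.arange(n)
        walk = [frontier.copy()]
        alive = np.ones(n, dtype=bool)
        cur = frontier.copy()
        for _ in range(walk_length - 1):
            lo, hi = starts[cur], starts[cur + 1]
            has_next = alive & (hi > lo)
            nxt = cur.copy()
            idx = np.nonzero(has_next)[0]
            if len(idx) == 0:
                break
            pick = lo[idx] + rng.integers(0, hi[idx] - lo[idx])
            nxt[idx] = dst_sorted[pick]
            alive = has_next
            cur = nxt
            step = np.where(alive, cur, -1)
            walk.append(step)
        walks.append(np.stack(walk, axis=1))  # (n, L)
    corpus = np.vstack(walks)

    # (center, context) pairs within the window
    pairs = []
    L = corpus.shape[1]
    for offset in range(1, context + 1):
        if offset >= L:
            break
        c = corpus[:, :-offset].ravel()
        o = corpus[:, offset:].ravel()
        ok = (c >= 0) & (o >= 0)
        pairs.append(np.stack([c[ok], o[ok]], axis=1))
        pairs.append(np.stack([o[ok], c[ok]], axis=1))
    pairs = np.vstack(pairs)
    if len(pairs) == 0:
        warnings.warn("no co-occurrence pairs generated; returning zeros")
        return np.zeros((n, d_emb))

    counts = np.bincount(corpus[corpus >= 0].ravel(), minlength=n).astype(float)
    noise = counts ** 0.75
    noise /= noise.sum()

    Win = (rng.random((n, d_emb)) - 0.5) / d_emb
    Wout = np.zeros((n, d_emb))
    # batch small relative to the vocabulary: within-batch duplicate updates
    # accumulate at stale parameters and overshoot otherwise
    batch = max(16, min(1024, n))
    for epoch in range(epochs):
        perm = rng.permutation(len(pairs))
        cur_lr = lr * max(1e-4, 1.0 - epoch / max(epochs, 1))
        for a in range(0, len(pairs), batch):
            sel = perm[a:a + batch]
            c, o = pairs[sel, 0], pairs[sel, 1]
            neg = rng.choice(n, size=(len(sel), n_negatives), p=noise)
            vc = Win[c]                                # (B, d)
            vo = Wout[o]
            logit_pos = np.clip((vc * vo).sum(axis=1), -12.0, 12.0)
            s_pos = 1.0 / (1.0 + np.exp(-logit_pos))
            g_pos = (s_pos - 1.0)[:, None]
            vneg = Wout[neg]                           # (B, k, d)
            logit_neg = np.clip((vneg * vc[:, None, :]).sum(axis=2), -12.0, 12.0)
            s_neg = 1.0 / (1.0 + np.exp(-logit_neg))
            grad_c = g_pos * vo + (s_neg[:, :, None] * vneg).sum(axis=1)
            np.add.at(Win, c, -cur_lr * grad_c)
            np.add.at(Wout, o, -cur_lr * g_pos * vc)
            np.add.at(Wout, neg.ravel(),
                      -cur_lr * (s_neg[:, :, None] * vc[:, None, :]).reshape(-1, d_emb))
    trained = np.zeros(n, dtype=bool)
    trained[np.unique(pairs)] = True
    Win[~trained] = 0.0
    return Win
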