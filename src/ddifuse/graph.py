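"""Network-structure channel: hierarchical LINE embedding of the DDI graph.

The known-interaction graph (built from training-fold positive pairs only)
is embedded with the second-order LINE objective

    O2 = - sum_{(i,j) in E} w_ij * log p2(v_j | v_i),
    p2(v_j | v_i) = exp(u'_j . u_i) / sum_k exp(u'_k . u_i),

optimised by edge-sampling SGD with degree^0.75 negative sampling.  To
capture global structure the graph is first coarsened (star collapsing of
leaf pairs sharing a hub, then edge collapsing by a random matching, per
level), the coarsest level is embedded from scratch, and each finer level
is initialised from its supernodes' vectors and refined ("prolongation").

Drugs absent from the training graph fall back to a neighbour's vector, or
to the zero vector when fully isolated.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)


def build_graph(edges, node_universe=None) -> nx.Graph:
    """Build an undirected, simple, weighted interaction graph.

    Duplicate and reversed pairs merge into one edge of weight 1 (or the
    given weight); self-pairs are dropped with a warning; drugs in
    ``node_universe`` without edges are kept as isolated nodes.
    """
    g = nx.Graph()
    if node_universe is not None:
        g.add_nodes_from(node_universe)
    for e in edges:
        if len(e) == 3:
            a, b, w = e
            w = float(w)
        else:
            a, b = e
            w = 1.0
        if a == b:
            warnings.warn(f"self-interaction pair ({a},{a}) dropped")
            continue
        if g.has_edge(a, b):
            # duplicates collapse to a single unit-weight edge
            continue
        g.add_edge(a, b, weight=w)
    return g


@dataclass
class CoarseningHierarchy:
    """Graphs G_0 (original) ... G_L (coarsest) with per-level node maps.

    ``maps[k]`` sends every node of ``levels[k]`` onto its supernode in
    ``levels[k+1]``; the composition sends every original node to exactly
    one coarsest supernode.
    """

    levels: list[nx.Graph]
    maps: list[dict]

    def __len__(self) -> int:
        return len(self.levels)

    def project(self, node, to_level: int):
        """Image of an original (level-0) node at ``to_level``."""
        cur = node
        for k in range(to_level):
            cur = self.maps[k][cur]
        return cur


def _apply_mapping(g: nx.Graph, mapping: dict) -> nx.Graph:
    """Quotient graph under a node->supernode map; merged weights sum."""
    h = nx.Graph()
    h.add_nodes_from(set(mapping.values()))
    for u, v, data in g.edges(data=True):
        mu, mv = mapping[u], mapping[v]
        if mu == mv:
            continue
        w = data.get("weight", 1.0)
        if h.has_edge(mu, mv):
            h[mu][mv]["weight"] += w
        else:
            h.add_edge(mu, mv, weight=w)
    return h


def _star_collapse_map(g: nx.Graph) -> dict:
    """Pair up degree-1 neighbours of each hub (HARP star collapsing)."""
    mapping = {n: n for n in g.nodes}
    deg = dict(g.degree)
    merged: set = set()
    for hub in sorted(g.nodes, key=lambda n: (-deg[n], str(n))):
        if deg[hub] < 2:
            continue
        leaves = sorted((nb for nb in g.neighbors(hub)
                         if deg[nb] == 1 and nb not in merged), key=str)
        for a, b in zip(leaves[0::2], leaves[1::2]):
            rep = min(a, b, key=str)
            other = b if rep is a else a
            mapping[other] = rep
            merged.add(a)
            merged.add(b)
    return mapping


def _edge_collapse_map(g: nx.Graph, rng: np.random.Generator) -> dict:
    """Random-matching edge collapsing: merge unmatched edge endpoints."""
    mapping = {n: n for n in g.nodes}
    matched: set = set()
    edges = sorted(g.edges, key=lambda e: (str(e[0]), str(e[1])))
    order = rng.permutation(len(edges))
    for k in order:
        u, v = edges[k]
        if u in matched or v in matched:
            continue
        rep = min(u, v, key=str)
        other = v if rep is u else u
        mapping[other] = rep
        matched.add(u)
        matched.add(v)
    return mapping


def coarsen(g: nx.Graph, threshold: int, seed: int = 0) -> CoarseningHierarchy:
    """Collapse the graph level by level until at most ``threshold`` nodes.

    Each level applies a star-collapsing pass followed by an
    edge-collapsing pass; merged-edge weights are summed.  Stops when the
    node count is within the threshold or a full level yields no
    reduction, so level sizes strictly decrease.
    """
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    rng = np.random.default_rng(seed)
    levels = [g]
    maps: list[dict] = []
    cur = g
    while cur.number_of_nodes() > threshold:
        m1 = _star_collapse_map(cur)
        g1 = _apply_mapping(cur, m1)
        m2 = _edge_collapse_map(g1, rng)
        g2 = _apply_mapping(g1, m2)
        if g2.number_of_nodes() >= cur.number_of_nodes():
            break
        combined = {n: m2[m1[n]] for n in cur.nodes}
        levels.append(g2)
        maps.append(combined)
        cur = g2
    return CoarseningHierarchy(levels=levels, maps=maps)


@dataclass
class NodeEmbedding:
    """Vertex and context vector tables over an embedded graph's nodes."""

    nodes: list
    vertex: np.ndarray   # (n, d) u_i
    context: np.ndarray  # (n, d) u'_j
    index: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.index:
            self.index = {n: i for i, n in enumerate(self.nodes)}

    @property
    def dim(self) -> int:
        return self.vertex.shape[1]

    def __contains__(self, node) -> bool:
        return node in self.index

    def vector(self, node) -> np.ndarray:
        return self.vertex[self.index[node]]


def second_order_probabilities(emb: NodeEmbedding) -> np.ndarray:
    """Exact softmax p2(. | v_i) for every source vertex; rows sum to 1."""
    logits = emb.vertex @ emb.context.T
    logits -= logits.max(axis=1, keepdims=True)
    p = np.exp(logits)
    return p / p.sum(axis=1, keepdims=True)


def line2_objective(g: nx.Graph, emb: NodeEmbedding) -> float:
    """Exact second-order objective O2 on a (small) graph.

    Each undirected edge contributes both directed orientations, weighted
    by the edge weight.
    """
    p = second_order_probabilities(emb)
    logp = np.log(np.clip(p, 1e-300, None))
    total = 0.0
    for u, v, data in g.edges(data=True):
        w = data.get("weight", 1.0)
        i, j = emb.index[u], emb.index[v]
        total -= w * (logp[i, j] + logp[j, i])
    return float(total)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -35.0, 35.0)))


def line2_embed(g: nx.Graph, dim: int = 64, init: NodeEmbedding | None = None,
                epochs: int = 100, neg_k: int = 5, lr: float = 0.025,
                batch_size: int = 1024, seed: int = 0) -> NodeEmbedding:
    """Second-order LINE by edge-sampling SGD with negative sampling.

    Edges are sampled proportionally to their weight, oriented at random;
    ``neg_k`` noise nodes per sample are drawn proportionally to
    degree^0.75.  The learning rate decays linearly to 1e-4 of its initial
    value.  When ``init`` is given, vertex/context vectors are warm-started
    from it (nodes missing from ``init`` get the cold-start values).
    """
    m = g.number_of_edges()
    if m == 0:
        raise ValueError("cannot embed: no edges")
    nodes = sorted(g.nodes, key=str)
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)

    rng = np.random.default_rng(seed)
    U = (rng.random((n, dim)) - 0.5) / dim
    Up = np.zeros((n, dim))
    if init is not None:
        for node, i in index.items():
            if node in init:
                j = init.index[node]
                U[i] = init.vertex[j]
                Up[i] = init.context[j]

    edges = np.array([(index[u], index[v]) for u, v in
                      sorted(g.edges, key=lambda e: (str(e[0]), str(e[1])))],
                     dtype=np.int64)
    w = np.array([g[u][v].get("weight", 1.0) for u, v in
                  sorted(g.edges, key=lambda e: (str(e[0]), str(e[1])))])
    edge_p = w / w.sum()
    deg = np.zeros(n)
    for (i, j), wij in zip(edges, w):
        deg[i] += wij
        deg[j] += wij
    noise = deg ** 0.75
    noise_p = noise / noise.sum()

    total = epochs * m
    # cap the batch so (a) there are enough SGD steps to anneal and (b) a
    # batch cannot re-sample the same edge many times with stale vectors,
    # which would amplify the effective step size on small graphs
    batch_size = min(batch_size, max(1, total // 200), max(1, m // 2))
    steps = max(math.ceil(total / batch_size), 1)
    lr_floor = 1e-4 * lr
    for s in range(steps):
        cur_lr = lr + (lr_floor - lr) * (s / steps)
        b = min(batch_size, total - s * batch_size)
        eidx = rng.choice(len(edges), size=b, p=edge_p)
        flip = rng.random(b) < 0.5
        src = np.where(flip, edges[eidx, 1], edges[eidx, 0])
        dst = np.where(flip, edges[eidx, 0], edges[eidx, 1])
        negs = rng.choice(n, size=(b, neg_k), p=noise_p)

        u = U[src]                               # (b, d)
        cpos = Up[dst]                           # (b, d)
        cneg = Up[negs]                          # (b, k, d)
        g_pos = _sigmoid((u * cpos).sum(1)) - 1.0        # (b,)
        g_neg = _sigmoid((cneg @ u[:, :, None])[..., 0])  # (b, k)

        du = g_pos[:, None] * cpos + (g_neg[:, :, None] * cneg).sum(1)
        dcpos = g_pos[:, None] * u
        dcneg = g_neg[:, :, None] * u[:, None, :]

        np.add.at(U, src, -cur_lr * du)
        np.add.at(Up, dst, -cur_lr * dcpos)
        np.add.at(Up, negs.ravel(), -cur_lr * dcneg.reshape(-1, dim))

    return NodeEmbedding(nodes=nodes, vertex=U, context=Up, index=index)


def harp_embed(g: nx.Graph, dim: int = 64, threshold: int | None = None,
               epochs: int = 100, neg_k: int = 5, lr: float = 0.025,
               batch_size: int = 1024, seed: int = 0,
               return_hierarchy: bool = False):
    """Coarsen / embed / refine: LINE with hierarchical initialisation.

    The coarsest level is embedded from a random start; each finer level
    initialises every node with its supernode's vertex and context vectors
    and refines with :func:`line2_embed`.  A hierarchy of length one is
    exactly a plain LINE run with the same seed.
    """
    if threshold is None:
        threshold = max(100, math.ceil(g.number_of_nodes() / 32))
    hier = coarsen(g, threshold=threshold, seed=seed)
    logger.info("coarsening hierarchy: %s nodes per level (threshold %d)",
                [lv.number_of_nodes() for lv in hier.levels], threshold)
    if len(hier) == 1:
        emb = line2_embed(g, dim=dim, epochs=epochs, neg_k=neg_k, lr=lr,
                          batch_size=batch_size, seed=seed)
        return (emb, hier) if return_hierarchy else emb

    emb = line2_embed(hier.levels[-1], dim=dim, epochs=epochs, neg_k=neg_k,
                      lr=lr, batch_size=batch_size, seed=seed)
    for level in range(len(hier) - 2, -1, -1):
        fine = hier.levels[level]
        mapping = hier.maps[level]
        nodes = sorted(fine.nodes, key=str)
        V = np.array([emb.vector(mapping[n]) for n in nodes])
        C = np.array([emb.context[emb.index[mapping[n]]] for n in nodes])
        init = NodeEmbedding(nodes=nodes, vertex=V, context=C)
        emb = line2_embed(fine, dim=dim, init=init, epochs=epochs,
                          neg_k=neg_k, lr=lr, batch_size=batch_size,
                          seed=seed + 1 + level)
    return (emb, hier) if return_hierarchy else emb


def embed_or_fallback(drug, g_train: nx.Graph,
                      emb: NodeEmbedding) -> np.ndarray:
    """Embedding vector with the unseen-node fallback.

    An embedded drug returns its own vector.  A drug missing from the
    embedding but with at least one embedded neighbour in the training
    graph copies the lexicographically smallest such neighbour's vector;
    a fully isolated drug gets the zero vector.
    """
    if drug in emb:
        return emb.vector(drug).copy()
    if drug in g_train:
        nbrs = sorted((nb for nb in g_train.neighbors(drug) if nb in emb),
                      key=str)
        if nbrs:
            return emb.vector(nbrs[0]).copy()
    return np.zeros(emb.dim)


class HarpLineEmbedder:
    """Estimator wrapper around :func:`harp_embed`.

    ``fit`` takes an interaction graph (or an edge list) and learns vertex
    vectors; ``transform`` maps drug ids to vectors using the unseen-node
    fallback rules.
    """

    def __init__(self, dim=64, threshold=None, epochs=100, neg_k=5,
                 lr=0.025, batch_size=1024, seed=0):
        self.dim = dim
        self.threshold = threshold
        self.epochs = epochs
        self.neg_k = neg_k
        self.lr = lr
        self.batch_size = batch_size
        self.seed = seed

    def get_params(self, deep=True):
        return {k: getattr(self, k) for k in
                ("dim", "threshold", "epochs", "neg_k", "lr",
                 "batch_size", "seed")}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, X, y=None):
        g = X if isinstance(X, nx.Graph) else build_graph(X)
        self.graph_ = g
        self.embedding_, self.hierarchy_ = harp_embed(
            g, dim=self.dim, threshold=self.threshold, epochs=self.epochs,
            neg_k=self.neg_k, lr=self.lr, batch_size=self.batch_size,
            seed=self.seed, return_hierarchy=True)
        return self

    def transform(self, drug_ids) -> np.ndarray:
        if not hasattr(self, "embedding_"):
            raise ValueError("HarpLineEmbedder is not fitted")
        return np.array([embed_or_fallback(d, self.graph_, self.embedding_)
                         for d in drug_ids])
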