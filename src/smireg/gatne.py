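"""Attributed multiplex heterogeneous network embedding (GATNE-style).

Every vertex i of type z with attribute vector x_i gets, per relation layer r,

    v_{i,r} = b_i + alpha_r * M_r^T U_i c_{i,r} + beta_r * D_z^T x_i

where

* b_i = h_z(x_i) is the base embedding (a per-type linear map, shared across
  relations),
* U_i = (u_{i,1}, ..., u_{i,m}) stacks the per-relation edge embeddings,
  each obtained from the initial edge embedding u^{(0)}_{i,r} = g_{z,r}(x_i)
  by K rounds of mean aggregation over the vertex's neighbourhood N_{i,r}
  (a vertex without neighbours in a layer keeps its own previous-level
  vector),
* c_{i,r} = softmax(w_r^T tanh(W_r U_i))^T is a self-attention weighting of
  the m edge-embedding columns,
* D_z^T x_i injects the raw attributes directly.

Training contexts come from meta-path random walks on each layer (next
vertex uniform over the neighbours of the prescribed next type) and the
parameters minimise the skip-gram negative-sampling objective

    E = -log sigma(c_j . v_{i,r}) - sum_{l=1}^{L} E_{k ~ P_t} [log sigma(-c_k . v_{i,r})]

with noise vertices drawn from the unigram^{3/4} distribution restricted to
the centre vertex's type. All gradients are derived analytically and checked
against numerical differentiation in the test suite.

A transductive variant replaces h_z(x_i) and g_{z,r}(x_i) with free
per-vertex parameter tables and drops the attribute term, embedding network
structure only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._sampling import AliasSampler
from .exceptions import ValidationError
from .io_network import MultiplexGraph

logger = logging.getLogger(__name__)

_CLIP = 30.0


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -_CLIP, _CLIP)))


def _log_sigmoid(x):
    return -np.logaddexp(0.0, -np.clip(x, -_CLIP, _CLIP))


@dataclass(frozen=True)
class GatneConfig:
    """Hyperparameters of the multiplex embedding.

    dim: overall embedding dimension d; edge_dim: edge-embedding dimension s;
    att_dim: attention hidden size a; K: aggregation depth; alpha/beta: edge-
    and attribute-term weights of the fusion equation. Walk and skip-gram
    settings follow word2vec conventions.
    """

    dim: int = 128
    edge_dim: int = 64
    att_dim: int = 20
    K: int = 1
    alpha: float = 1.0
    beta: float = 1.0
    meta_path: tuple[str, ...] = ("sm", "mir")
    walk_length: int = 10
    walks_per_vertex: int = 20
    window: int = 5
    negatives: int = 5
    epochs: int = 50
    lr: float = 0.01
    batch_size: int = 256


@dataclass
class WalkCorpus:
    """Vertex-index sequences walked on one relation layer."""

    walks: list[list[int]]
    relation: str
    meta_path: tuple[str, ...]
    vertices: list[str]  # index -> vertex id mapping used by the walks


class _GraphIndex:
    """Dense indexed view of a MultiplexGraph used by the trainer."""

    def __init__(self, graph: MultiplexGraph, K: int):
        self.graph = graph
        self.vertices = list(graph.vertices)
        self.index = {v: i for i, v in enumerate(self.vertices)}
        self.n = len(self.vertices)
        self.types = sorted({graph.node_type(v) for v in self.vertices})
        self.type_of = np.array([self.types.index(graph.node_type(v)) for v in self.vertices])
        self.relations = graph.relations
        self.adj = {
            r: [np.array([self.index[u] for u in graph.neighbors(v, r)], dtype=int)
                for v in self.vertices]
            for r in self.relations
        }
        # per-type attribute matrices with zero rows for the other type(s)
        self.X: dict[str, np.ndarray] = {}
        for zi, z in enumerate(self.types):
            dz = graph.attribute_dim(z)
            X = np.zeros((self.n, dz))
            for i, v in enumerate(self.vertices):
                if self.type_of[i] == zi:
                    X[i] = graph.attributes[v]
            self.X[z] = X
        # P_r = A_r^K with A_r the row-normalised adjacency (self-row if no neighbours)
        self.P: dict[str, np.ndarray] = {}
        for r in self.relations:
            A = np.zeros((self.n, self.n))
            for i in range(self.n):
                nb = self.adj[r][i]
                if len(nb):
                    A[i, nb] = 1.0 / len(nb)
                else:
                    A[i, i] = 1.0
            self.P[r] = np.linalg.matrix_power(A, K)


class GatneModel:
    """Parameter container for the multiplex embedding (inductive or transductive)."""

    def __init__(
        self,
        graph: MultiplexGraph,
        config: GatneConfig,
        seed: int = 0,
        mode: str = "inductive",
    ):
        if config.K < 0:
            raise ValidationError("aggregation depth K must be >= 0")
        if mode not in ("inductive", "transductive"):
            raise ValidationError(f"unknown mode {mode!r}")
        self.config = config
        self.mode = mode
        self.gi = _GraphIndex(graph, config.K)
        self.relations = self.gi.relations
        self.m = len(self.relations)
        rng = np.random.default_rng(seed)
        d, s, a = config.dim, config.edge_dim, config.att_dim
        n = self.gi.n

        def xavier(shape):
            fan = shape[0] + shape[-1]
            return rng.normal(0.0, np.sqrt(2.0 / fan), size=shape)

        p: dict[tuple, np.ndarray] = {}
        if mode == "inductive":
            for z in self.gi.types:
                dz = self.gi.X[z].shape[1]
                p[("H", z)] = xavier((d, dz))
                p[("D", z)] = xavier((dz, d))
                for r in self.relations:
                    p[("G", z, r)] = xavier((s, dz))
        else:
            p[("B",)] = rng.uniform(-0.5 / d, 0.5 / d, size=(n, d))
            for r in self.relations:
                p[("U0", r)] = rng.uniform(-0.5 / s, 0.5 / s, size=(n, s))
        for r in self.relations:
            p[("Wr", r)] = xavier((a, s))
            p[("wr", r)] = xavier((a,))
            p[("Mr", r)] = xavier((s, d))
        p[("Ctx",)] = rng.uniform(-0.5 / d, 0.5 / d, size=(n, d))
        self.params = p

    # ---------------------------------------------------------------- forward

    def forward(self) -> dict:
        """Compute all per-vertex, per-relation embeddings plus intermediates."""
        gi, cfg = self.gi, self.config
        U0, UK = {}, {}
        for r in self.relations:
            if self.mode == "inductive":
                u0 = np.zeros((gi.n, cfg.edge_dim))
                for z in gi.types:
                    u0 += gi.X[z] @ self.params[("G", z, r)].T
            else:
                u0 = self.params[("U0", r)]
            U0[r] = u0
            UK[r] = gi.P[r] @ u0
        Ustack = np.stack([UK[r] for r in self.relations], axis=2)  # (n, s, m)
        if self.mode == "inductive":
            B = np.zeros((gi.n, cfg.dim))
            for z in gi.types:
                B += gi.X[z] @ self.params[("H", z)].T
        else:
            B = self.params[("B",)]
        T, att, V = {}, {}, {}
        for r in self.relations:
            pre = np.einsum("as,nsm->nam", self.params[("Wr", r)], Ustack)
            Tr = np.tanh(pre)
            logits = np.einsum("a,nam->nm", self.params[("wr", r)], Tr)
            e = np.exp(logits - logits.max(axis=1, keepdims=True))
            ar = e / e.sum(axis=1, keepdims=True)
            y = np.einsum("nsm,nm->ns", Ustack, ar)
            v = B + cfg.alpha * y @ self.params[("Mr", r)]
            if self.mode == "inductive":
                for z in gi.types:
                    v = v + cfg.beta * gi.X[z] @ self.params[("D", z)]
            T[r], att[r], V[r] = Tr, ar, v
        return {"U0": U0, "UK": UK, "Ustack": Ustack, "B": B, "T": T, "att": att, "V": V}

    def embeddings(self) -> dict[tuple[str, str], np.ndarray]:
        """{(vertex, relation): v_{i,r}} for every vertex and relation."""
        V = self.forward()["V"]
        return {
            (v, r): V[r][i].copy()
            for r in self.relations
            for i, v in enumerate(self.gi.vertices)
        }

    # ------------------------------------------------------ loss and gradients

    def loss_and_grads(
        self, batch: Sequence[tuple[str, int, int, np.ndarray]], fw: dict | None = None
    ) -> tuple[float, dict[tuple, np.ndarray]]:
        """Skip-gram negative-sampling loss and analytic parameter gradients.

        ``batch`` holds (relation, center index, context index, negative index
        array) tuples. Gradients cover every parameter group; contexts and
        negatives update the shared context-embedding table.
        """
        if fw is None:
            fw = self.forward()
        gi, cfg = self.gi, self.config
        Ctx = self.params[("Ctx",)]
        grads: dict[tuple, np.ndarray] = {k: np.zeros_like(v) for k, v in self.params.items()}
        loss = 0.0
        dUstack = np.zeros_like(fw["Ustack"])
        Gv_by_r: dict[str, np.ndarray] = {}
        by_r: dict[str, list] = {}
        for item in batch:
            by_r.setdefault(item[0], []).append(item)
        for r, items in by_r.items():
            centers = np.array([it[1] for it in items])
            ctxs = np.array([it[2] for it in items])
            negs = np.stack([np.asarray(it[3], dtype=int) for it in items])
            v = fw["V"][r][centers]
            pos = np.einsum("bd,bd->b", v, Ctx[ctxs])
            neg = np.einsum("bd,bld->bl", v, Ctx[negs])
            loss += float(-(_log_sigmoid(pos)).sum() - _log_sigmoid(-neg).sum())
            gpos = _sigmoid(pos) - 1.0
            gneg = _sigmoid(neg)
            gv = gpos[:, None] * Ctx[ctxs] + np.einsum("bl,bld->bd", gneg, Ctx[negs])
            np.add.at(grads[("Ctx",)], ctxs, gpos[:, None] * v)
            np.add.at(
                grads[("Ctx",)],
                negs.ravel(),
                (gneg[:, :, None] * v[:, None, :]).reshape(-1, cfg.dim),
            )
            Gv = np.zeros((gi.n, cfg.dim))
            np.add.at(Gv, centers, gv)
            Gv_by_r[r] = Gv
        # backprop the fused embedding for each relation that appeared
        for r, Gv in Gv_by_r.items():
            # base term
            if self.mode == "inductive":
                for z in gi.types:
                    grads[("H", z)] += Gv.T @ gi.X[z]
                    grads[("D", z)] += cfg.beta * gi.X[z].T @ Gv
            else:
                grads[("B",)] += Gv
            # edge term: v += alpha * y @ Mr
            att = fw["att"][r]
            y = np.einsum("nsm,nm->ns", fw["Ustack"], att)
            grads[("Mr", r)] += cfg.alpha * y.T @ Gv
            Gy = cfg.alpha * Gv @ self.params[("Mr", r)].T  # (n, s)
            dUstack += Gy[:, :, None] * att[:, None, :]
            datt = np.einsum("nsm,ns->nm", fw["Ustack"], Gy)
            # softmax backprop
            dz = att * (datt - (att * datt).sum(axis=1, keepdims=True))
            Tr = fw["T"][r]
            grads[("wr", r)] += np.einsum("nam,nm->a", Tr, dz)
            dpre = (self.params[("wr", r)][None, :, None] * dz[:, None, :]) * (1.0 - Tr ** 2)
            grads[("Wr", r)] += np.einsum("nam,nsm->as", dpre, fw["Ustack"])
            dUstack += np.einsum("as,nam->nsm", self.params[("Wr", r)], dpre)
        # aggregation backprop, per edge-embedding column
        for mi, r in enumerate(self.relations):
            dUK = dUstack[:, :, mi]
            if not np.any(dUK):
                continue
            dU0 = gi.P[r].T @ dUK
            if self.mode == "inductive":
                for z in gi.types:
                    grads[("G", z, r)] += dU0.T @ gi.X[z]
            else:
                grads[("U0", r)] += dU0
        if not np.isfinite(loss):
            raise FloatingPointError("non-finite skip-gram loss")
        return loss, grads


# ------------------------------------------------------------- spec operations


def base_embedding(model: GatneModel, x: np.ndarray, z: str) -> np.ndarray:
    """b_i = h_z(x_i): the relation-shared linear transform of the attributes."""
    H = model.params[("H", z)]
    x = np.asarray(x, float)
    if x.shape[0] != H.shape[1]:
        raise ValidationError(f"attribute dim {x.shape[0]} != transform input dim {H.shape[1]}")
    return H @ x


def aggregate_edge_embedding(
    graph: MultiplexGraph, model: GatneModel, vertex: str, relation: str, K: int
) -> np.ndarray:
    """K rounds of mean neighbourhood aggregation from u^{(0)}_{i,r} = g_{z,r}(x_i).

    Direct recursive implementation over the graph; a vertex without
    neighbours in the layer keeps its previous-level vector.
    """
    if K < 0:
        raise ValidationError("K must be >= 0")
    levels: dict[str, np.ndarray] = {}
    for v in graph.vertices:
        z = graph.node_type(v)
        levels[v] = model.params[("G", z, relation)] @ graph.attributes[v]
    for _ in range(K):
        nxt = {}
        for v in graph.vertices:
            nbrs = graph.neighbors(v, relation)
            if nbrs:
                nxt[v] = np.mean([levels[u] for u in nbrs], axis=0)
            else:
                nxt[v] = levels[v]
        levels = nxt
    return levels[vertex]


def attention_coefficients(model: GatneModel, U_i: np.ndarray, relation: str) -> np.ndarray:
    """c_{i,r} = softmax(w_r^T tanh(W_r U_i)); positive, sums to 1 over the m columns."""
    U_i = np.asarray(U_i, float)
    if U_i.ndim != 2 or U_i.shape[1] != model.m:
        raise ValidationError(f"U_i must be s x m = {model.config.edge_dim} x {model.m}")
    logits = model.params[("wr", relation)] @ np.tanh(model.params[("Wr", relation)] @ U_i)
    e = np.exp(logits - logits.max())
    return e / e.sum()


def node_embedding(
    model: GatneModel, graph: MultiplexGraph, vertex: str, relation: str
) -> np.ndarray:
    """Fused embedding v_{i,r} = b_i + alpha M_r^T U_i c_{i,r} + beta D_z^T x_i."""
    cfg = model.config
    z = graph.node_type(vertex)
    x = graph.attributes[vertex]
    b = base_embedding(model, x, z)
    U_i = np.stack(
        [aggregate_edge_embedding(graph, model, vertex, r, cfg.K) for r in model.relations],
        axis=1,
    )
    c = attention_coefficients(model, U_i, relation)
    v = b + cfg.alpha * model.params[("Mr", relation)].T @ (U_i @ c)
    v = v + cfg.beta * model.params[("D", z)].T @ x
    return v


def generate_walks(
    graph: MultiplexGraph,
    meta_path: Sequence[str],
    length: int,
    walks_per_vertex: int,
    relation: str,
    seed: int = 0,
) -> WalkCorpus:
    """Meta-path random walks on one relation layer.

    The next vertex is drawn uniformly from the current vertex's neighbours of
    the next type prescribed by the (cyclic) meta path; the walk truncates
    early when that set is empty. Start vertices whose type does not occur in
    the meta path are skipped with a warning.
    """
    meta_path = tuple(meta_path)
    gi_vertices = list(graph.vertices)
    index = {v: i for i, v in enumerate(gi_vertices)}
    types = [graph.node_type(v) for v in gi_vertices]
    rng = np.random.default_rng(seed)
    walks: list[list[int]] = []
    skipped = 0
    for start_i, start in enumerate(gi_vertices):
        z = types[start_i]
        if z not in meta_path:
            skipped += 1
            continue
        offset = meta_path.index(z)
        for _ in range(walks_per_vertex):
            walk = [start_i]
            cur = start
            for step in range(1, length):
                want = meta_path[(offset + step) % len(meta_path)]
                cands = [u for u in graph.neighbors(cur, relation) if graph.node_type(u) == want]
                if not cands:
                    break
                cur = cands[int(rng.integers(0, len(cands)))]
                walk.append(index[cur])
            walks.append(walk)
    if skipped:
        logger.warning("skipped %d start vertices whose type is absent from the meta path", skipped)
    return WalkCorpus(walks=walks, relation=relation, meta_path=meta_path, vertices=gi_vertices)


def _skipgram_pairs(corpus: WalkCorpus, window: int) -> list[tuple[int, int]]:
    pairs = []
    for walk in corpus.walks:
        for c, center in enumerate(walk):
            lo, hi = max(0, c - window), min(len(walk), c + window + 1)
            for t in range(lo, hi):
                if t != c:
                    pairs.append((center, walk[t]))
    return pairs


def _noise_samplers(
    corpora: Sequence[WalkCorpus], gi: _GraphIndex
) -> dict[int, tuple[AliasSampler, np.ndarray]]:
    """Per-type unigram^{3/4} noise distributions over corpus vertex occurrences."""
    counts = np.zeros(gi.n)
    for corpus in corpora:
        for walk in corpus.walks:
            for v in walk:
                counts[v] += 1
    samplers = {}
    for zi, z in enumerate(gi.types):
        members = np.where(gi.type_of == zi)[0]
        w = counts[members] ** 0.75
        if w.sum() == 0:
            w = np.ones_like(w)
        samplers[zi] = (AliasSampler(w), members)
    return samplers


def train_gatne(
    graph: MultiplexGraph,
    corpora: WalkCorpus | Sequence[WalkCorpus],
    config: GatneConfig = GatneConfig(),
    seed: int = 0,
    mode: str = "inductive",
) -> dict[tuple[str, str], np.ndarray]:
    """Train the multiplex embedding on walk corpora by seeded minibatch SGD.

    Returns {(vertex, relation): vector} for every vertex and relation layer.
    With zero epochs the initialised model's embeddings are returned.
    """
    if isinstance(corpora, WalkCorpus):
        corpora = [corpora]
    model = GatneModel(graph, config, seed=seed, mode=mode)
    for corpus in corpora:
        if corpus.vertices != model.gi.vertices:
            raise ValidationError("walk corpus indexes a different vertex set than the graph")
    train_model(model, corpora, seed=seed + 1)
    return model.embeddings()


def train_model(model: GatneModel, corpora: Sequence[WalkCorpus], seed: int = 0) -> list[float]:
    """SGD loop over skip-gram pairs; returns mean per-pair loss per epoch."""
    cfg = model.config
    gi = model.gi
    pairs: list[tuple[str, int, int]] = []
    for corpus in corpora:
        for center, ctx in _skipgram_pairs(corpus, cfg.window):
            pairs.append((corpus.relation, center, ctx))
    if not pairs or cfg.epochs == 0:
        return []
    samplers = _noise_samplers(corpora, gi)
    rng = np.random.default_rng(seed)
    history = []
    order = np.arange(len(pairs))
    for _epoch in range(cfg.epochs):
        rng.shuffle(order)
        total = 0.0
        for lo in range(0, len(order), cfg.batch_size):
            chunk = order[lo : lo + cfg.batch_size]
            batch = []
            for pi in chunk:
                r, center, ctx = pairs[pi]
                sampler, members = samplers[gi.type_of[center]]
                negs = members[sampler.draw(rng, cfg.negatives)]
                batch.append((r, center, ctx, negs))
            loss, grads = model.loss_and_grads(batch)
            total += loss
            scale = cfg.lr / len(batch)  # mean-gradient step
            for k, g in grads.items():
                model.params[k] -= scale * g
        history.append(total / len(order))
    logger.info("skip-gram training: %d pairs, epoch losses %s",
                len(pairs), [f"{h:.4f}" for h in history])
    return history


def inductive_embed(
    graph: MultiplexGraph, config: GatneConfig = GatneConfig(), seed: int = 0
) -> dict[tuple[str, str], np.ndarray]:
    """Walk generation + inductive training in one call (one corpus per layer)."""
    corpora = [
        generate_walks(graph, config.meta_path, config.walk_length,
                       config.walks_per_vertex, r, seed=seed + 101 + k)
        for k, r in enumerate(graph.relations)
    ]
    return train_gatne(graph, corpora, config, seed=seed, mode="inductive")


def transductive_embed(
    graph: MultiplexGraph, config: GatneConfig = GatneConfig(), seed: int = 0
) -> dict[tuple[str, str], np.ndarray]:
    """Structure-only variant: free per-vertex base/edge tables, no attribute input."""
    corpora = [
        generate_walks(graph, config.meta_path, config.walk_length,
                       config.walks_per_vertex, r, seed=seed + 101 + k)
        for k, r in enumerate(graph.relations)
    ]
    return train_gatne(graph, corpora, config, seed=seed, mode="transductive")
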