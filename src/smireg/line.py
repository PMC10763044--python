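"""Proximity-preserving embedding of the weighted self-similarity networks (LINE).

Two objectives are trained separately and concatenated:

* first-order proximity: for every undirected edge (i, j) the joint model
  probability p1(v_i, v_j) = sigma(u_i . u_j) is pulled toward the empirical
  edge distribution w_ij / W, giving O1 = -sum_(i,j) w_ij log p1(v_i, v_j);
* second-order proximity: every undirected edge is treated as two directed
  edges and the context-conditional softmax
  p2(v_j | v_i) = exp(u'_j . u_i) / sum_k exp(u'_k . u_i)
  is pulled toward w_ij / d_i, giving O2 = -sum_(i,j) w_ij log p2(v_j | v_i),
  where each vertex's KL term is weighted by its prestige d_i (its weighted
  degree), which cancels against the empirical distribution's normaliser.

Optimisation follows the canonical recipe: weighted edge sampling through an
alias table plus negative sampling (K noise vertices per positive drawn from
the degree^{3/4} distribution), with a linearly decayed learning rate.
line_objective evaluates the exact objectives (full softmax for order 2) and
serves as the slow reference the trainer is tested against.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from ._sampling import AliasSampler
from .exceptions import ValidationError
from .similarity import SimilarityMatrix

logger = logging.getLogger(__name__)

_CLIP = 30.0  # exponent clip for the sigmoid


@dataclass
class WeightedGraph:
    """Undirected weighted graph; edges stored once with i < j."""

    vertices: list[str]
    edges: np.ndarray  # (E, 2) int indices into vertices
    weights: np.ndarray  # (E,) positive

    def __post_init__(self):
        self.edges = np.asarray(self.edges, dtype=int).reshape(-1, 2)
        self.weights = np.asarray(self.weights, dtype=float).reshape(-1)
        if np.any(self.weights <= 0):
            raise ValidationError("edge weights must be positive")
        if np.any(self.edges[:, 0] == self.edges[:, 1]):
            raise ValidationError("self-loops are not allowed")

    @property
    def n(self) -> int:
        return len(self.vertices)

    @property
    def total_weight(self) -> float:
        """W: sum of weights over undirected edges."""
        return float(self.weights.sum())

    def degrees(self) -> np.ndarray:
        """Weighted degree d_i of every vertex."""
        d = np.zeros(self.n)
        np.add.at(d, self.edges[:, 0], self.weights)
        np.add.at(d, self.edges[:, 1], self.weights)
        return d


def build_similarity_graph(sim: SimilarityMatrix, min_weight: float = 0.0) -> WeightedGraph:
    """Weighted graph from a similarity matrix: edge (i, j) iff S_ij > min_weight.

    The diagonal is discarded. Vertices left isolated get a logged warning and
    will receive a zero embedding.
    """
    n = len(sim.ids)
    iu, ju = np.triu_indices(n, k=1)
    mask = sim.S[iu, ju] > min_weight
    edges = np.column_stack([iu[mask], ju[mask]])
    weights = sim.S[iu, ju][mask]
    g = WeightedGraph(vertices=list(sim.ids), edges=edges, weights=weights)
    isolated = sorted(set(range(n)) - set(edges.ravel().tolist()))
    if isolated:
        logger.warning(
            "similarity graph has %d isolated vertices (zero embeddings): %s",
            len(isolated), [sim.ids[i] for i in isolated[:10]],
        )
    return g


def _sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -_CLIP, _CLIP)))


def line_p1(u_i: np.ndarray, u_j: np.ndarray) -> float:
    """First-order joint probability sigma(u_i . u_j)."""
    u_i, u_j = np.asarray(u_i, float), np.asarray(u_j, float)
    if u_i.shape != u_j.shape:
        raise ValidationError("embedding dimension mismatch")
    return float(_sigmoid(u_i @ u_j))


def line_objective(
    graph: WeightedGraph,
    emb: Mapping[str, np.ndarray],
    order: int,
    context: Mapping[str, np.ndarray] | None = None,
) -> float:
    """Exact objective: O1, or O2 with the full softmax over all vertices.

    This is the reference quantity (no negative-sampling approximation);
    training only ever decreases it relative to the initial model.
    """
    if len(graph.weights) == 0:
        raise ValidationError("graph has no edges")
    U = np.stack([np.asarray(emb[v], float) for v in graph.vertices])
    i, j, w = graph.edges[:, 0], graph.edges[:, 1], graph.weights
    if order == 1:
        scores = np.einsum("ed,ed->e", U[i], U[j])
        return float(-(w * np.log(_sigmoid(scores))).sum())
    if order == 2:
        if context is None:
            raise ValidationError("order-2 objective requires context vectors")
        C = np.stack([np.asarray(context[v], float) for v in graph.vertices])
        logits = U @ C.T  # (n, n): logits[a, b] = u'_b . u_a
        logits -= logits.max(axis=1, keepdims=True)
        logp = logits - np.log(np.exp(logits).sum(axis=1, keepdims=True))
        # each undirected edge contributes both directions
        return float(-(w * logp[i, j]).sum() - (w * logp[j, i]).sum())
    raise ValidationError(f"order must be 1 or 2, got {order}")


def negative_sampling_loss_and_grads(
    center: np.ndarray, targets: np.ndarray, labels: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """Skip-gram negative-sampling loss for one center against labelled targets.

    loss = -sum_t [ l_t log sigma(c . t) + (1 - l_t) log sigma(-c . t) ].
    Returns (loss, grad wrt center, grad wrt each target row). Shared by both
    proximity orders (order 1 uses vertex vectors as targets, order 2 context
    vectors) and checked against numerical differentiation in the tests.
    """
    center = np.asarray(center, float)
    targets = np.atleast_2d(np.asarray(targets, float))
    labels = np.asarray(labels, float).reshape(-1)
    scores = targets @ center
    p = _sigmoid(scores)
    eps = 1e-12
    loss = -(labels * np.log(p + eps) + (1 - labels) * np.log(1 - p + eps)).sum()
    g = p - labels  # d loss / d score
    grad_center = g @ targets
    grad_targets = np.outer(g, center)
    return float(loss), grad_center, grad_targets


def _directed_edges(graph: WeightedGraph) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Each undirected edge as two directed edges with the same weight."""
    src = np.concatenate([graph.edges[:, 0], graph.edges[:, 1]])
    dst = np.concatenate([graph.edges[:, 1], graph.edges[:, 0]])
    w = np.concatenate([graph.weights, graph.weights])
    return src, dst, w


def train_line(
    graph: WeightedGraph,
    dim: int,
    order: int,
    epochs: int = 50,
    negatives: int = 5,
    lr: float = 0.025,
    seed: int = 0,
    batch_size: int = 128,
    full_output: bool = False,
):
    """Train one proximity order by alias edge sampling + negative sampling SGD.

    One epoch draws as many directed-edge samples as there are directed edges.
    Deterministic given the seed. Returns {vertex: vector}; with
    ``full_output`` also the order-2 context table.
    """
    if dim < 2:
        raise ValidationError(f"dim must be >= 2, got {dim}")
    if order not in (1, 2):
        raise ValidationError(f"order must be 1 or 2, got {order}")
    rng = np.random.default_rng(seed)
    n = graph.n
    U = rng.uniform(-0.5 / dim, 0.5 / dim, size=(n, dim))
    C = np.zeros((n, dim))  # order-2 context table
    deg = graph.degrees()
    connected = deg > 0
    if len(graph.weights) > 0 and epochs > 0:
        src, dst, w = _directed_edges(graph)
        edge_sampler = AliasSampler(w)
        noise = np.where(connected, deg, 0.0) ** 0.75
        noise_sampler = AliasSampler(noise)
        total = epochs * len(src)
        done = 0
        targets = U if order == 1 else C
        while done < total:
            b = min(batch_size, total - done)
            step_lr = lr * max(1e-4, 1.0 - done / total)
            e = edge_sampler.draw(rng, b)
            ci, tj = src[e], dst[e]
            negs = noise_sampler.draw(rng, (b, negatives))
            # scores for positive and negative targets
            pos_score = np.einsum("bd,bd->b", U[ci], targets[tj])
            neg_score = np.einsum("bd,bkd->bk", U[ci], targets[negs])
            gpos = _sigmoid(pos_score) - 1.0
            gneg = _sigmoid(neg_score)
            grad_center = gpos[:, None] * targets[tj] + np.einsum("bk,bkd->bd", gneg, targets[negs])
            grad_pos = gpos[:, None] * U[ci]
            grad_neg = gneg[:, :, None] * U[ci][:, None, :]
            if not np.all(np.isfinite(grad_center)):
                raise FloatingPointError("non-finite gradient in proximity-embedding SGD")
            np.add.at(U, ci, -step_lr * grad_center)
            np.add.at(targets, tj, -step_lr * grad_pos)
            np.add.at(targets, negs.ravel(), -step_lr * grad_neg.reshape(-1, dim))
            done += b
    U = np.where(connected[:, None], U, 0.0)
    emb = {v: U[i].copy() for i, v in enumerate(graph.vertices)}
    if full_output:
        ctx = {v: C[i].copy() for i, v in enumerate(graph.vertices)}
        return emb, ctx
    return emb


def combine_orders(
    e1: Mapping[str, np.ndarray], e2: Mapping[str, np.ndarray]
) -> dict[str, np.ndarray]:
    """Concatenate first-order (first block) and second-order embeddings."""
    if set(e1) != set(e2):
        diff = sorted(set(e1) ^ set(e2))
        raise ValidationError(f"vertex sets differ: {diff}")
    return {v: np.concatenate([np.asarray(e1[v], float), np.asarray(e2[v], float)]) for v in e1}


def line_attributes(
    sim: SimilarityMatrix,
    dim: int = 64,
    epochs: int = 50,
    negatives: int = 5,
    lr: float = 0.025,
    seed: int = 0,
    min_weight: float = 0.0,
) -> dict[str, np.ndarray]:
    """First- plus second-order embeddings of a self-similarity network.

    Each order is trained at ``dim`` dimensions and the results concatenated
    (combined attribute dimension 2*dim; the default 64+64 gives 128).
    """
    graph = build_similarity_graph(sim, min_weight=min_weight)
    e1 = train_line(graph, dim=dim, order=1, epochs=epochs, negatives=negatives, lr=lr, seed=seed)
    e2 = train_line(graph, dim=dim, order=2, epochs=epochs, negatives=negatives, lr=lr, seed=seed + 1)
    return combine_orders(e1, e2)
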