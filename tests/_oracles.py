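"""Independent brute-force reference implementations used only by tests.

Everything here is written as plain loops from the defining formulas, kept
deliberately separate from the package's vectorised code paths.
"""

import math

import numpy as np


def sigmoid(x):
    return 1.0 / (1.0 + math.exp(-x))


def brute_force_o1(graph, emb):
    """First-order objective: -sum over undirected edges of w * log sigma(u_i . u_j)."""
    total = 0.0
    for (i, j), w in zip(graph.edges, graph.weights):
        vi, vj = graph.vertices[i], graph.vertices[j]
        score = float(np.dot(emb[vi], emb[vj]))
        total -= w * math.log(sigmoid(score))
    return total


def brute_force_p2(graph, emb, ctx, i):
    """Full-softmax context distribution p2(. | v_i) over all vertices."""
    vi = graph.vertices[i]
    scores = [float(np.dot(ctx[graph.vertices[k]], emb[vi])) for k in range(graph.n)]
    mx = max(scores)
    exps = [math.exp(s - mx) for s in scores]
    z = sum(exps)
    return [e / z for e in exps]


def brute_force_o2(graph, emb, ctx):
    """Second-order objective with both directions of every undirected edge."""
    total = 0.0
    for (i, j), w in zip(graph.edges, graph.weights):
        for a, b in ((i, j), (j, i)):
            p = brute_force_p2(graph, emb, ctx, a)[b]
            total -= w * math.log(p)
    return total


def concordance_auc(scores, labels):
    """AUC as the normalised concordant-pair count, 0.5 credit per tie."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def recursive_mean_aggregate(graph, init, vertex, relation, K):
    """K rounds of neighbourhood mean aggregation from per-vertex init vectors."""
    if K == 0:
        return np.asarray(init[vertex], dtype=float)
    nbrs = graph.neighbors(vertex, relation)
    if not nbrs:
        return recursive_mean_aggregate(graph, init, vertex, relation, K - 1)
    vals = [recursive_mean_aggregate(graph, init, u, relation, K - 1) for u in nbrs]
    return np.mean(vals, axis=0)


def mean_tanimoto_pool(positives, fps, sm_ids, mirna_ids, threshold):
    """Exhaustive eligible-pool enumeration straight from the definitions."""
    pos_pairs = {(e.sm_id, e.mirna_id) for e in positives}
    regulators = {}
    for e in positives:
        regulators.setdefault(e.mirna_id, set()).add(e.sm_id)
    pool = set()
    for m in mirna_ids:
        regs = regulators.get(m)
        if not regs:
            continue
        for s in sm_ids:
            if (s, m) in pos_pairs:
                continue
            vals = []
            for r in sorted(regs):
                a, b = fps[s].bits, fps[r].bits
                union = len(a | b)
                vals.append(len(a & b) / union if union else 0.0)
            if sum(vals) / len(vals) < threshold:
                pool.add((s, m))
    return pool
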