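import math

import numpy as np
import pytest

from _oracles import recursive_mean_aggregate
from smireg.exceptions import ValidationError
from smireg.gatne import (
    GatneConfig,
    GatneModel,
    aggregate_edge_embedding,
    attention_coefficients,
    base_embedding,
    generate_walks,
    node_embedding,
    train_gatne,
    transductive_embed,
)
from smireg.io_network import RegulationEdge, RegulationEdgeSet, build_multiplex_graph


def toy_graph(seed=0, two_relations=True):
    edges = [
        RegulationEdge("s1", "m1", "up"),
        RegulationEdge("s1", "m2", "up"),
        RegulationEdge("s2", "m2", "up"),
        RegulationEdge("s3", "m3", "up"),
    ]
    if two_relations:
        edges += [
            RegulationEdge("s2", "m1", "down"),
            RegulationEdge("s1", "m3", "down"),
            RegulationEdge("s3", "m2", "down"),
        ]
    rng = np.random.default_rng(seed)
    attrs = {f"sm:s{i}": rng.normal(size=5) for i in (1, 2, 3)}
    attrs.update({f"mir:m{i}": rng.normal(size=4) for i in (1, 2, 3)})
    return build_multiplex_graph(RegulationEdgeSet(edges), attrs)


def small_config(**kw):
    defaults = dict(dim=6, edge_dim=5, att_dim=3, K=1, walk_length=6,
                    walks_per_vertex=4, window=2, negatives=2, epochs=1, batch_size=16)
    defaults.update(kw)
    return GatneConfig(**defaults)


class TestBaseEmbedding:
    def test_identity_transform(self):
        g = toy_graph()
        model = GatneModel(g, small_config(), seed=1)
        model.params[("H", "sm")] = np.eye(5)[:5]
        x = np.eye(5)[0]
        assert np.array_equal(base_embedding(model, x, "sm"), x)

    def test_zero_attributes_give_zero(self):
        g = toy_graph()
        model = GatneModel(g, small_config(), seed=1)
        assert np.array_equal(base_embedding(model, np.zeros(5), "sm"), np.zeros(6))

    def test_linearity(self):
        g = toy_graph()
        model = GatneModel(g, small_config(), seed=1)
        x = np.arange(5.0)
        assert np.allclose(base_embedding(model, 2 * x, "sm"), 2 * base_embedding(model, x, "sm"))


class TestAggregation:
    def test_k0_is_initial_transform(self):
        g = toy_graph()
        model = GatneModel(g, small_config(), seed=2)
        for v in g.vertices:
            z = g.node_type(v)
            expected = model.params[("G", z, "up")] @ g.attributes[v]
            assert np.allclose(aggregate_edge_embedding(g, model, v, "up", 0), expected)

    def test_star_center_mean_of_identical_leaves(self):
        edges = RegulationEdgeSet([RegulationEdge("hub", f"m{i}", "up") for i in range(3)])
        attrs = {"sm:hub": np.array([5.0, -1.0])}
        attrs.update({f"mir:m{i}": np.array([1.0, 2.0]) for i in range(3)})
        g = build_multiplex_graph(edges, attrs)
        model = GatneModel(g, small_config(), seed=3)
        c = model.params[("G", "mir", "up")] @ np.array([1.0, 2.0])
        assert np.allclose(aggregate_edge_embedding(g, model, "sm:hub", "up", 1), c)

    def test_matches_recursive_oracle_at_k2(self):
        g = toy_graph(seed=4)
        model = GatneModel(g, small_config(K=2), seed=4)
        for r in g.relations:
            init = {v: model.params[("G", g.node_type(v), r)] @ g.attributes[v] for v in g.vertices}
            for v in g.vertices:
                expected = recursive_mean_aggregate(g, init, v, r, 2)
                assert np.allclose(aggregate_edge_embedding(g, model, v, r, 2), expected, atol=1e-10)

    def test_forward_consistent_with_per_vertex_path(self):
        g = toy_graph(seed=5)
        model = GatneModel(g, small_config(K=2), seed=5)
        fw = model.forward()
        for r in model.relations:
            for i, v in enumerate(model.gi.vertices):
                assert np.allclose(fw["UK"][r][i], aggregate_edge_embedding(g, model, v, r, 2),
                                   atol=1e-10)

    def test_negative_k_rejected(self):
        g = toy_graph()
        model = GatneModel(g, small_config(), seed=0)
        with pytest.raises(ValidationError):
            aggregate_edge_embedding(g, model, "sm:s1", "up", -1)


class TestAttention:
    def test_identical_columns_give_uniform(self):
        g = toy_graph()
        model = GatneModel(g, small_config(), seed=6)
        U = np.tile(np.arange(5.0)[:, None], (1, 2))
        c = attention_coefficients(model, U, "up")
        assert np.allclose(c, [0.5, 0.5])

    def test_single_relation_gives_one(self):
        g = toy_graph(two_relations=False)
        model = GatneModel(g, small_config(), seed=6)
        c = attention_coefficients(model, np.random.default_rng(0).normal(size=(5, 1)), "up")
        assert np.allclose(c, [1.0])

    def test_closed_form_logits(self):
        g = toy_graph()
        model = GatneModel(g, small_config(att_dim=1), seed=6)
        model.params[("wr", "up")] = np.array([1.0])
        W = np.zeros((1, 5))
        W[0, 0] = 1.0
        model.params[("Wr", "up")] = W
        U = np.zeros((5, 2))
        U[0, 0] = math.atanh(math.log(2.0))  # logits become (ln 2, 0)
        c = attention_coefficients(model, U, "up")
        assert np.allclose(c, [2 / 3, 1 / 3])

    def test_sums_to_one_everywhere(self):
        g = toy_graph(seed=7)
        model = GatneModel(g, small_config(), seed=7)
        fw = model.forward()
        for r in model.relations:
            assert np.allclose(fw["att"][r].sum(axis=1), 1.0)
            assert np.all(fw["att"][r] > 0)


class TestNodeEmbedding:
    def test_alpha_beta_zero_reduces_to_base(self):
        g = toy_graph(seed=8)
        model = GatneModel(g, small_config(alpha=0.0, beta=0.0), seed=8)
        for v in g.vertices:
            b = base_embedding(model, g.attributes[v], g.node_type(v))
            assert np.allclose(node_embedding(model, g, v, "up"), b)

    def test_alpha_zero_isolates_attribute_term(self):
        g = toy_graph(seed=8)
        model = GatneModel(g, small_config(alpha=0.0, beta=2.0), seed=8)
        v = "sm:s1"
        x = g.attributes[v]
        expected = model.params[("H", "sm")] @ x + 2.0 * model.params[("D", "sm")].T @ x
        assert np.allclose(node_embedding(model, g, v, "up"), expected)

    def test_full_expression_matches_manual_arithmetic(self):
        g = toy_graph(seed=9)
        cfg = small_config(alpha=0.7, beta=0.3, K=1)
        model = GatneModel(g, cfg, seed=9)
        v = "mir:m2"
        x = g.attributes[v]
        # manual term-by-term composition
        U = np.stack(
            [aggregate_edge_embedding(g, model, v, r, 1) for r in model.relations], axis=1
        )
        logits = model.params[("wr", "up")] @ np.tanh(model.params[("Wr", "up")] @ U)
        e = np.exp(logits - logits.max())
        c = e / e.sum()
        manual = (
            model.params[("H", "mir")] @ x
            + 0.7 * model.params[("Mr", "up")].T @ (U @ c)
            + 0.3 * model.params[("D", "mir")].T @ x
        )
        assert np.allclose(node_embedding(model, g, v, "up"), manual, atol=1e-12)


class TestWalks:
    def test_all_transitions_legal(self):
        g = toy_graph(seed=10)
        for r in g.relations:
            corpus = generate_walks(g, ("sm", "mir"), 8, 5, r, seed=1)
            for walk in corpus.walks:
                for a, b in zip(walk, walk[1:]):
                    va, vb = corpus.vertices[a], corpus.vertices[b]
                    assert vb in g.neighbors(va, r)
                    assert g.node_type(va) != g.node_type(vb)

    def test_single_successor_is_deterministic(self):
        edges = RegulationEdgeSet([RegulationEdge("s1", "m1", "up")])
        attrs = {"sm:s1": np.ones(2), "mir:m1": np.ones(2)}
        g = build_multiplex_graph(edges, attrs)
        corpus = generate_walks(g, ("sm", "mir"), 4, 3, "up", seed=0)
        for walk in corpus.walks:
            assert len(set(walk[::2])) == 1 and len(set(walk[1::2])) == 1

    def test_two_successor_split_within_four_standard_errors(self):
        edges = RegulationEdgeSet(
            [RegulationEdge("s1", "m1", "up"), RegulationEdge("s1", "m2", "up")]
        )
        attrs = {"sm:s1": np.ones(2), "mir:m1": np.ones(2), "mir:m2": np.ones(2)}
        g = build_multiplex_graph(edges, attrs)
        corpus = generate_walks(g, ("sm", "mir"), 2, 10_000, "up", seed=3)
        first_steps = [w[1] for w in corpus.walks if corpus.vertices[w[0]] == "sm:s1"]
        n = len(first_steps)
        count = sum(1 for s in first_steps if corpus.vertices[s] == "mir:m1")
        se = math.sqrt(0.25 * n)
        assert abs(count - n / 2) <= 4 * se

    def test_wrong_type_start_skipped_with_warning(self, caplog):
        g = toy_graph()
        with caplog.at_level("WARNING"):
            corpus = generate_walks(g, ("sm",), 3, 2, "up", seed=0)
        assert any("skipped" in r.message for r in caplog.records)
        # sm-only meta path: walks start at SMs and stop immediately (no sm-sm edges)
        assert all(len(w) == 1 for w in corpus.walks)


class TestTraining:
    def test_pair_loss_closed_form_at_zero_scores(self):
        g = toy_graph(seed=11)
        model = GatneModel(g, small_config(), seed=11)
        model.params[("Ctx",)] = np.zeros_like(model.params[("Ctx",)])
        loss, _ = model.loss_and_grads([("up", 0, 1, np.array([2]))])
        assert loss == pytest.approx(2 * math.log(2.0))

    def test_zero_epochs_returns_initial_embeddings(self):
        g = toy_graph(seed=12)
        cfg = small_config(epochs=0)
        corpus = generate_walks(g, ("sm", "mir"), 6, 4, "up", seed=0)
        emb = train_gatne(g, corpus, cfg, seed=12)
        model = GatneModel(g, cfg, seed=12)
        for key, vec in model.embeddings().items():
            assert np.array_equal(emb[key], vec)

    def test_same_seed_bitwise_identical(self):
        g = toy_graph(seed=13)
        cfg = small_config(epochs=2)
        corpora = [generate_walks(g, ("sm", "mir"), 6, 4, r, seed=i) for i, r in enumerate(g.relations)]
        e1 = train_gatne(g, corpora, cfg, seed=13)
        e2 = train_gatne(g, corpora, cfg, seed=13)
        for k in e1:
            assert np.array_equal(e1[k], e2[k])

    @pytest.mark.parametrize("mode", ["inductive", "transductive"])
    def test_gradients_match_central_differences(self, mode):
        g = toy_graph(seed=14)
        model = GatneModel(g, small_config(), seed=14, mode=mode)
        rs = model.relations
        batch = [
            (rs[0], 0, 3, np.array([1, 4])),
            (rs[1], 2, 5, np.array([0, 3])),
            (rs[0], 3, 0, np.array([2, 5])),
            (rs[1], 5, 2, np.array([4, 1])),
        ]
        _, grads = model.loss_and_grads(batch)
        eps = 1e-6
        rng = np.random.default_rng(15)
        for key, grad in grads.items():
            p = model.params[key]
            flat = rng.choice(p.size, size=min(5, p.size), replace=False)
            for f in flat:
                idx = np.unravel_index(f, p.shape)
                orig = p[idx]
                p[idx] = orig + eps
                lp, _ = model.loss_and_grads(batch)
                p[idx] = orig - eps
                lm, _ = model.loss_and_grads(batch)
                p[idx] = orig
                num = (lp - lm) / (2 * eps)
                ana = grad[idx]
                assert abs(num - ana) / max(abs(num) + abs(ana), 1e-6) <= 1e-4, key

    def test_two_block_bipartite_structure_recovered(self):
        # planted two-block bipartite layer: block cosine separation after training
        edges, attrs = [], {}
        rng = np.random.default_rng(16)
        for b in range(2):
            for i in range(4):
                s, m = f"s{b}{i}", f"m{b}{i}"
                attrs[f"sm:{s}"] = rng.normal(size=4) + 3 * np.eye(4)[b]
                attrs[f"mir:{m}"] = rng.normal(size=4) + 3 * np.eye(4)[2 + b]
            for i in range(4):
                for j in range(4):
                    if (i + j) % 2 == 0:
                        edges.append(RegulationEdge(f"s{b}{i}", f"m{b}{j}", "up"))
        g = build_multiplex_graph(RegulationEdgeSet(edges), attrs)
        cfg = small_config(dim=8, edge_dim=6, epochs=10, walks_per_vertex=8, walk_length=8)
        for embed in (
            lambda: train_gatne(g, generate_walks(g, ("sm", "mir"), 8, 8, "up", seed=1), cfg, seed=2),
            lambda: transductive_embed(g, cfg, seed=2),
        ):
            emb = embed()
            V = {k: v / (np.linalg.norm(v) + 1e-12) for k, v in emb.items()}
            keys = sorted(V)
            within, between = [], []
            for i, (ka, _) in enumerate(keys):
                for kb, _ in keys[i + 1:]:
                    if ka[-2] == kb[-2] and ka[:3] == kb[:3]:
                        within.append(float(V[(ka, "up")] @ V[(kb, "up")]))
                    elif ka[:3] == kb[:3]:
                        between.append(float(V[(ka, "up")] @ V[(kb, "up")]))
            assert np.mean(within) > np.mean(between)


class TestTransductive:
    def test_independent_of_attributes(self):
        g1 = toy_graph(seed=20)
        # same topology, different attributes
        rng = np.random.default_rng(99)
        attrs2 = {v: rng.normal(size=g1.attributes[v].shape) for v in g1.vertices}
        edges = {r: g1.edges(r) for r in g1.relations}
        from smireg.io_network import MultiplexGraph

        g2 = MultiplexGraph(edges, attrs2)
        cfg = small_config(epochs=1)
        e1 = transductive_embed(g1, cfg, seed=5)
        e2 = transductive_embed(g2, cfg, seed=5)
        for k in e1:
            assert np.array_equal(e1[k], e2[k])

    def test_zero_steps_returns_initialisation(self):
        g = toy_graph(seed=21)
        cfg = small_config(epochs=0)
        emb = transductive_embed(g, cfg, seed=21)
        model = GatneModel(g, cfg, seed=21, mode="transductive")
        for key, vec in model.embeddings().items():
            assert np.array_equal(emb[key], vec)
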