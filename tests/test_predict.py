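import numpy as np
import pytest

from _oracles import concordance_auc
from smireg.exceptions import ValidationError
from smireg.io_network import mir_vertex, sm_vertex
from smireg.predict import (
    ConfusionCounts,
    confusion,
    cross_validate,
    fit_classifier,
    metrics,
    pair_features,
    rank_candidates,
    roc_pr,
    stratified_folds,
    PairFeatureTable,
)


def emb_table(sm_ids, mir_ids, dim=4, relation="up", seed=0):
    rng = np.random.default_rng(seed)
    emb = {}
    for s in sm_ids:
        emb[(sm_vertex(s), relation)] = rng.normal(size=dim)
    for m in mir_ids:
        emb[(mir_vertex(m), relation)] = rng.normal(size=dim)
    return emb


class TestPairFeatures:
    def test_width_is_twice_dim_mirna_block_first(self):
        emb = emb_table(["s1"], ["m1"])
        table = pair_features(emb, [("s1", "m1", 1)], "up")
        assert table.X.shape == (1, 8)
        assert np.array_equal(table.X[0, :4], emb[(mir_vertex("m1"), "up")])
        assert np.array_equal(table.X[0, 4:], emb[(sm_vertex("s1"), "up")])

    def test_zero_embeddings_give_zero_features(self):
        emb = {(sm_vertex("s1"), "up"): np.zeros(3), (mir_vertex("m1"), "up"): np.zeros(3)}
        table = pair_features(emb, [("s1", "m1", 0)], "up")
        assert not table.X.any()

    def test_missing_embedding_listed(self):
        emb = emb_table(["s1"], ["m1"])
        with pytest.raises(ValidationError, match="s2"):
            pair_features(emb, [("s2", "m1", 1)], "up")


class TestFitClassifier:
    def separable_table(self, n=60):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(-3, 0.3, size=(n // 2, 4)), rng.normal(3, 0.3, size=(n // 2, 4))])
        y = np.array([0] * (n // 2) + [1] * (n // 2))
        return PairFeatureTable(pairs=[("s", f"m{i}") for i in range(n)], X=X, y=y)

    def test_separable_training_accuracy(self):
        table = self.separable_table()
        model = fit_classifier(table, seed=0)
        assert (model.predict(table.X) == table.y).all()

    def test_same_seed_identical_predictions(self):
        table = self.separable_table()
        p1 = fit_classifier(table, seed=3).predict_proba(table.X)
        p2 = fit_classifier(table, seed=3).predict_proba(table.X)
        assert np.array_equal(p1, p2)

    @pytest.mark.parametrize("alt", ["rf", "lr", "nb", "svm"])
    def test_alternate_classifiers_share_interface(self, alt):
        table = self.separable_table(n=40)
        model = fit_classifier(table, classifier=alt, seed=0)
        probs = model.predict_proba(table.X)
        assert probs.shape == (40, 2)

    def test_single_class_rejected(self):
        table = self.separable_table()
        table.y[:] = 1
        with pytest.raises(ValidationError):
            fit_classifier(table)


class TestConfusionAndMetrics:
    def test_perfect_scores(self):
        c = confusion(np.array([1.0, 1.0, 0.0, 0.0]), np.array([1, 1, 0, 0]))
        assert (c.TP, c.FP, c.TN, c.FN) == (2, 0, 2, 0)
        m = metrics(c)
        assert m == {"Acc": 1.0, "Sen": 1.0, "Spec": 1.0, "MCC": 1.0}

    def test_tie_at_threshold_counts_positive(self):
        c = confusion(np.full(6, 0.5), np.array([1, 1, 1, 0, 0, 0]))
        assert c.TN == 0 and c.FN == 0 and c.FP == 3 and c.TP == 3

    def test_hundred_pair_set_matches_manual_count(self):
        rng = np.random.default_rng(2)
        scores = rng.random(100)
        labels = rng.integers(0, 2, size=100)
        c = confusion(scores, labels, threshold=0.4)
        tp = sum(1 for s, l in zip(scores, labels) if s >= 0.4 and l == 1)
        fp = sum(1 for s, l in zip(scores, labels) if s >= 0.4 and l == 0)
        fn = sum(1 for s, l in zip(scores, labels) if s < 0.4 and l == 1)
        tn = sum(1 for s, l in zip(scores, labels) if s < 0.4 and l == 0)
        assert (c.TP, c.FP, c.TN, c.FN) == (tp, fp, tn, fn)

    def test_closed_form_mixed_counts(self):
        m = metrics(ConfusionCounts(TP=40, FN=10, TN=35, FP=15))
        assert m["Acc"] == pytest.approx(0.75)
        assert m["Sen"] == pytest.approx(0.8)
        assert m["Spec"] == pytest.approx(0.7)
        assert m["MCC"] == pytest.approx(1250 / np.sqrt(55 * 50 * 50 * 45))
        assert m["MCC"] == pytest.approx(0.5025, abs=5e-4)

    def test_zero_denominator_conventions(self):
        m = metrics(ConfusionCounts(TP=0, FN=10, TN=10, FP=0))
        assert m["Sen"] == 0.0 and m["Spec"] == 1.0 and m["MCC"] == 0.0

    def test_joint_permutation_invariance(self):
        rng = np.random.default_rng(3)
        scores = rng.random(50)
        labels = rng.integers(0, 2, size=50)
        perm = rng.permutation(50)
        assert metrics(confusion(scores, labels)) == metrics(confusion(scores[perm], labels[perm]))

    def test_non_binary_labels_rejected(self):
        with pytest.raises(ValidationError):
            confusion(np.array([0.5]), np.array([2]))


class TestRocPr:
    def test_perfect_separation(self):
        out = roc_pr(np.array([0.9, 0.8, 0.2, 0.1]), np.array([1, 1, 0, 0]))
        assert out["AUC"] == 1.0 and out["AUPR"] == 1.0

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(4)
        scores = rng.random(5000)
        labels = rng.integers(0, 2, size=5000)
        assert roc_pr(scores, labels)["AUC"] == pytest.approx(0.5, abs=0.05)

    def test_auc_equals_concordance_count(self):
        rng = np.random.default_rng(5)
        for n in (6, 37, 200):
            scores = np.round(rng.random(n), 2)  # induce ties
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            assert roc_pr(scores, labels)["AUC"] == pytest.approx(
                concordance_auc(scores, labels), abs=1e-12
            )

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            roc_pr(np.array([0.1, 0.9]), np.array([1, 1]))


class TestCrossValidate:
    def _pairs(self, n_pos=25, n_neg=25):
        sm_ids = [f"s{i}" for i in range(10)]
        mir_ids = [f"m{i}" for i in range(10)]
        rng = np.random.default_rng(6)
        pairs = []
        seen = set()
        while len(pairs) < n_pos + n_neg:
            s, m = rng.choice(sm_ids), rng.choice(mir_ids)
            if (s, m) in seen:
                continue
            seen.add((s, m))
            pairs.append((str(s), str(m), 1 if len(pairs) < n_pos else 0))
        return sm_ids, mir_ids, pairs

    def test_stratified_fold_sizes(self):
        y = np.array([1] * 23 + [0] * 22)
        folds = stratified_folds(y, 5, seed=0)
        for f in folds:
            assert abs(np.sum(y[f] == 1) - 23 / 5) < 1
            assert abs(np.sum(y[f] == 0) - 22 / 5) < 1
        assert sorted(np.concatenate(folds).tolist()) == list(range(45))

    def test_report_mean_is_fold_mean(self):
        sm_ids, mir_ids, pairs = self._pairs()
        emb = emb_table(sm_ids, mir_ids, seed=7)
        report = cross_validate(pairs, "up", lambda tp: emb, k=5, seed=8, classifier="nb")
        accs = [f["Acc"] for f in report.folds]
        assert report.mean("Acc") == pytest.approx(float(np.mean(accs)), abs=1e-12)
        assert len(report.folds) == 5
        for f in report.folds:
            for m in ("Acc", "Sen", "Spec", "AUC", "AUPR"):
                assert 0.0 <= f[m] <= 1.0
            assert -1.0 <= f["MCC"] <= 1.0

    def test_embed_fn_receives_only_training_positives(self):
        sm_ids, mir_ids, pairs = self._pairs()
        emb = emb_table(sm_ids, mir_ids, seed=9)
        n_pos_total = sum(1 for _, _, l in pairs if l == 1)
        seen_sizes = []

        def embed(train_pos):
            seen_sizes.append(len(train_pos))
            return emb

        cross_validate(pairs, "up", embed, k=5, seed=10, classifier="nb")
        assert all(size < n_pos_total for size in seen_sizes)
        assert sum(n_pos_total - size for size in seen_sizes) == n_pos_total


class TestRankCandidates:
    class _ConstantModel:
        def __init__(self, probs):
            self.probs = probs

        def predict_proba(self, X):
            p = np.asarray(self.probs[: len(X)])
            return np.column_stack([1 - p, p])

    def test_descending_order(self):
        emb = emb_table(["s1"], ["m1", "m2", "m3"])
        model = self._ConstantModel([0.2, 0.9, 0.5])
        ranked = rank_candidates(model, emb, "s1", ["m1", "m2", "m3"], "up")
        assert [m for m, _ in ranked] == ["m2", "m3", "m1"]

    def test_ties_break_lexicographically(self):
        emb = emb_table(["s1"], ["mb", "ma", "mc"])
        model = self._ConstantModel([0.5, 0.5, 0.5])
        ranked = rank_candidates(model, emb, "s1", ["mb", "ma", "mc"], "up")
        assert [m for m, _ in ranked] == ["ma", "mb", "mc"]

    def test_top_k_truncation(self):
        mirs = [f"m{i}" for i in range(15)]
        emb = emb_table(["s1"], mirs)
        model = self._ConstantModel(list(np.linspace(0, 1, 15)))
        assert len(rank_candidates(model, emb, "s1", mirs, "up", top=10)) == 10

    def test_unknown_id_rejected(self):
        emb = emb_table(["s1"], ["m1"])
        with pytest.raises(ValidationError):
            rank_candidates(self._ConstantModel([0.5]), emb, "s1", ["m-missing"], "up")
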