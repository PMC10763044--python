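"""Pair features, gradient-boosted link classification, CV and metrics.

A candidate (SM, miRNA) pair under relation r is represented by the
concatenation [v_miRNA ; v_SM] of the two endpoint embeddings for that
relation (miRNA block first; the order is frozen for reproducibility).
Classification defaults to LightGBM (leaf-wise gradient-boosted trees);
logistic regression, naive Bayes, SVM and random forest are drop-in
alternates behind the same interface.

Cross-validation is stratified by splitting positives and negatives
independently into k folds. For every fold the embedding is retrained with
the fold's positive edges removed from the graph (they would otherwise leak
label information through the walks), so ``cross_validate`` takes a callback
that maps a training edge set to an embedding table.

Metrics: Acc = (TP+TN)/N, Sen = TP/(TP+FN), Spec = TN/(TN+FP), MCC with the
zero-denominator -> 0 convention, plus ROC/PR curves with trapezoidal AUC
and step-interpolated AUPR.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from sklearn.metrics import (
    average_precision_score,
    precision_recall_curve,
    roc_auc_score,
    roc_curve,
)

from .exceptions import ValidationError
from .io_network import RegulationEdge, RegulationEdgeSet, mir_vertex, sm_vertex

logger = logging.getLogger(__name__)


@dataclass
class PairFeatureTable:
    """Labelled (SM, miRNA) pairs with concatenated embedding features."""

    pairs: list[tuple[str, str]]  # (sm_id, mirna_id), raw ids
    X: np.ndarray  # (n, 2d)
    y: np.ndarray  # (n,) in {0, 1}

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass
class CvReport:
    """Per-fold and aggregate fivefold cross-validation results."""

    folds: list[dict] = field(default_factory=list)  # per-fold metric dicts

    METRICS = ("Acc", "Sen", "Spec", "MCC", "AUC", "AUPR")

    def mean(self, metric: str) -> float:
        return float(np.mean([f[metric] for f in self.folds]))

    def sd(self, metric: str) -> float:
        return float(np.std([f[metric] for f in self.folds], ddof=1))

    def summary(self) -> dict:
        return {
            m: {"mean": self.mean(m), "sd": self.sd(m)} for m in self.METRICS
        }

    def to_dict(self) -> dict:
        folds = []
        for f in self.folds:
            row = {k: v for k, v in f.items() if k in self.METRICS}
            row["n_test"] = f["n_test"]
            folds.append(row)
        return {"folds": folds, "summary": self.summary()}

    def curve_rows(self) -> list[tuple]:
        """(fold, curve, x, y) rows for the ROC and PR point lists."""
        rows = []
        for k, f in enumerate(self.folds):
            for x, y in zip(*f["roc_points"]):
                rows.append((k, "roc", float(x), float(y)))
            for x, y in zip(*f["pr_points"]):
                rows.append((k, "pr", float(x), float(y)))
        return rows


def pair_features(
    emb: Mapping[tuple[str, str], np.ndarray],
    pairs: Sequence[tuple[str, str, int]],
    relation: str,
) -> PairFeatureTable:
    """Feature table with rows [v_miRNA ; v_SM] for labelled raw-id pairs."""
    feats, labels, out_pairs, missing = [], [], [], []
    for sm_id, mirna_id, label in pairs:
        ks, km = (sm_vertex(sm_id), relation), (mir_vertex(mirna_id), relation)
        if ks not in emb or km not in emb:
            missing.extend([k[0] for k in (ks, km) if k not in emb])
            continue
        feats.append(np.concatenate([emb[km], emb[ks]]))
        labels.append(label)
        out_pairs.append((sm_id, mirna_id))
    if missing:
        raise ValidationError(f"missing embeddings for vertices: {sorted(set(missing))}")
    return PairFeatureTable(pairs=out_pairs, X=np.asarray(feats), y=np.asarray(labels, dtype=int))


_CLASSIFIERS = ("lightgbm", "rf", "lr", "nb", "svm")


def fit_classifier(
    table: PairFeatureTable,
    classifier: str = "lightgbm",
    seed: int = 0,
    params: dict | None = None,
):
    """Fit the link classifier; alternates share the predict_proba interface."""
    if len(np.unique(table.y)) < 2:
        raise ValidationError("training table must contain both classes")
    params = dict(params or {})
    if classifier == "lightgbm":
        from lightgbm import LGBMClassifier

        defaults = dict(
            n_estimators=500, num_leaves=31, learning_rate=0.05,
            random_state=seed, deterministic=True, n_jobs=1, verbose=-1,
        )
        defaults.update(params)
        model = LGBMClassifier(**defaults)
    elif classifier == "rf":
        from sklearn.ensemble import RandomForestClassifier

        model = RandomForestClassifier(n_estimators=500, random_state=seed, n_jobs=1, **params)
    elif classifier == "lr":
        from sklearn.linear_model import LogisticRegression

        model = LogisticRegression(max_iter=2000, random_state=seed, **params)
    elif classifier == "nb":
        from sklearn.naive_bayes import GaussianNB

        model = GaussianNB(**params)
    elif classifier == "svm":
        from sklearn.svm import SVC

        model = SVC(probability=True, random_state=seed, **params)
    else:
        raise ValidationError(f"unknown classifier {classifier!r}; choose from {_CLASSIFIERS}")
    model.fit(table.X, table.y)
    return model


def confusion(scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5) -> ConfusionCounts:
    """Confusion counts with the score >= threshold rule (tie counts positive)."""
    scores = np.asarray(scores, float).reshape(-1)
    labels = np.asarray(labels).reshape(-1)
    if scores.shape != labels.shape:
        raise ValidationError("scores and labels must have equal length")
    if not set(np.unique(labels)) <= {0, 1}:
        raise ValidationError("labels must be binary 0/1")
    calls = scores >= threshold
    pos = labels == 1
    return ConfusionCounts(
        TP=int(np.sum(calls & pos)),
        FP=int(np.sum(calls & ~pos)),
        TN=int(np.sum(~calls & ~pos)),
        FN=int(np.sum(~calls & pos)),
    )


def metrics(counts: ConfusionCounts) -> dict[str, float]:
    """Accuracy, sensitivity, specificity and MCC from confusion counts.

    Any zero denominator (in Sen, Spec or MCC) yields 0 by convention.
    """
    if counts.total == 0:
        raise ValidationError("empty confusion counts")
    tp, fp, tn, fn = counts.TP, counts.FP, counts.TN, counts.FN
    acc = (tp + tn) / counts.total
    sen = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = (tp * tn - fp * fn) / denom if denom else 0.0
    return {"Acc": acc, "Sen": sen, "Spec": spec, "MCC": mcc}


def roc_pr(scores: np.ndarray, labels: np.ndarray) -> dict:
    """ROC and PR curves with AUC (trapezoidal) and AUPR (step interpolation)."""
    scores = np.asarray(scores, float).reshape(-1)
    labels = np.asarray(labels).reshape(-1)
    if len(set(labels.tolist())) < 2:
        raise ValidationError("both classes must be present to draw ROC/PR curves")
    fpr, tpr, _ = roc_curve(labels, scores)
    prec, rec, _ = precision_recall_curve(labels, scores)
    return {
        "AUC": float(roc_auc_score(labels, scores)),
        "AUPR": float(average_precision_score(labels, scores)),
        "roc_points": (fpr.tolist(), tpr.tolist()),
        "pr_points": (rec.tolist(), prec.tolist()),
    }


def stratified_folds(y: np.ndarray, k: int, seed: int) -> list[np.ndarray]:
    """Split positives and negatives independently into k near-equal folds."""
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    for label in (1, 0):
        idx = np.where(y == label)[0]
        if len(idx) < k:
            raise ValidationError(f"class {label} has {len(idx)} members, need >= k = {k}")
        rng.shuffle(idx)
        for f, part in enumerate(np.array_split(idx, k)):
            folds[f].extend(part.tolist())
    return [np.array(sorted(f)) for f in folds]


EmbedFn = Callable[[RegulationEdgeSet], Mapping[tuple[str, str], np.ndarray]]


def cross_validate(
    pairs: Sequence[tuple[str, str, int]],
    relation: str,
    embed_fn: EmbedFn,
    k: int = 5,
    seed: int = 0,
    classifier: str = "lightgbm",
    classifier_params: dict | None = None,
    threshold: float = 0.5,
) -> CvReport:
    """Stratified k-fold CV with per-fold embedding retraining.

    ``embed_fn`` receives the training-fold positive edges only (the test
    fold's positives are masked from the embedding graph) and returns the
    {(vertex, relation): vector} table used to featurise both partitions.
    """
    if k < 2:
        raise ValidationError("k must be >= 2")
    y = np.array([label for _, _, label in pairs], dtype=int)
    folds = stratified_folds(y, k, seed)
    report = CvReport()
    for fold_id, test_idx in enumerate(folds):
        test_mask = np.zeros(len(pairs), dtype=bool)
        test_mask[test_idx] = True
        train = [p for i, p in enumerate(pairs) if not test_mask[i]]
        test = [p for i, p in enumerate(pairs) if test_mask[i]]
        if len({label for _, _, label in test}) < 2:
            raise ValidationError(f"fold {fold_id} contains a single class")
        train_pos = RegulationEdgeSet(
            [RegulationEdge(s, m, relation) for s, m, label in train if label == 1]
        )
        emb = embed_fn(train_pos)
        table_train = pair_features(emb, train, relation)
        table_test = pair_features(emb, test, relation)
        model = fit_classifier(table_train, classifier=classifier, seed=seed, params=classifier_params)
        scores = model.predict_proba(table_test.X)[:, 1]
        fold = metrics(confusion(scores, table_test.y, threshold))
        fold.update(roc_pr(scores, table_test.y))
        fold["n_test"] = len(test)
        report.folds.append(fold)
        logger.info(
            "fold %d: Acc %.4f Sen %.4f Spec %.4f MCC %.4f AUC %.4f AUPR %.4f",
            fold_id, fold["Acc"], fold["Sen"], fold["Spec"], fold["MCC"],
            fold["AUC"], fold["AUPR"],
        )
    return report


def rank_candidates(
    model,
    emb: Mapping[tuple[str, str], np.ndarray],
    sm_id: str,
    candidate_mirnas: Sequence[str],
    relation: str,
    top: int | None = None,
) -> list[tuple[str, float]]:
    """Candidate miRNAs ranked by predicted regulation probability.

    Descending by probability; exact ties break lexicographically by id.
    """
    table = pair_features(emb, [(sm_id, m, 0) for m in candidate_mirnas], relation)
    probs = model.predict_proba(table.X)[:, 1]
    ranked = sorted(zip(candidate_mirnas, probs), key=lambda t: (-t[1], t[0]))
    ranked = [(m, float(p)) for m, p in ranked]
    return ranked[:top] if top is not None else ranked
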