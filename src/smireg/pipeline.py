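"""Orchestration of the five pipeline stages, configuration and artifacts.

Stages, in order: (1) read the study and build the regulation layers;
(2) Tanimoto self-similarity networks for SMs and miRNAs, plus balanced
negative sampling below the proximity-score threshold; (3) proximity
embedding (LINE) of both similarity networks to produce node attributes;
(4) multiplex heterogeneous network embedding (GATNE) of the attributed
regulation graph; (5) pair featurisation and gradient-boosted
classification under stratified fivefold cross-validation, with the test
fold's positive edges masked from the embedding graph.

Ablation modes are config switches sharing one code path:

* ``full``        — similarity-derived attributes + multiplex embedding;
* ``gatne_only``  — attributes replaced by one-hot identity vectors, so the
  embedding sees network structure only;
* ``attrs_only``  — the similarity-derived attributes are fed straight to
  the classifier, no multiplex embedding;
* ``transductive``— free per-vertex embeddings trained on structure alone
  (no attribute input at all).

Expensive, fold-independent stages (negatives, attributes) are cached
content-addressed under <outdir>/cache; cached values are always read back
so a cached and a fresh run produce byte-identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from . import line as line_mod
from .exceptions import ValidationError
from .gatne import GatneConfig, inductive_embed, transductive_embed
from .io_network import (
    RegulationEdgeSet,
    build_multiplex_graph,
    mir_vertex,
    read_edge_list,
    read_embeddings,
    read_mirna_fasta,
    read_sm_table,
    sm_vertex,
    write_edge_list,
    write_embeddings,
)
from .predict import CvReport, cross_validate, fit_classifier, pair_features, rank_candidates
from .similarity import (
    SimilarityMatrix,
    kmer_fingerprint,
    maccs_fingerprints,
    sample_negatives,
    similarity_matrix,
)
from .synthetic import read_fingerprint_sidecar

logger = logging.getLogger(__name__)

MODES = ("full", "gatne_only", "attrs_only", "transductive")


@dataclass(frozen=True)
class LineParams:
    dim: int = 64  # per order; concatenated attribute dim is 2 * dim
    epochs: int = 50
    negatives: int = 5
    lr: float = 0.025
    min_weight: float = 0.0


@dataclass(frozen=True)
class PipelineConfig:
    """Resolved configuration; sufficient to reproduce a run byte-for-byte."""

    sm_table: str = ""
    fingerprints: str = ""  # optional pre-computed sidecar; "" -> derive from SMILES
    mirna_fasta: str = ""
    edges: str = ""
    relation: str = "up"
    mode: str = "full"
    kmer: int = 4
    neg_threshold: float = 0.1
    folds: int = 5
    call_threshold: float = 0.5
    classifier: str = "lightgbm"
    classifier_params: dict = field(default_factory=dict)
    line: LineParams = LineParams()
    gatne: GatneConfig = GatneConfig(
        walks_per_vertex=10, walk_length=10, window=5, negatives=5, epochs=2, batch_size=512
    )
    seed: int = 7

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValidationError(f"mode must be one of {MODES}, got {self.mode!r}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        d = dict(d)
        if "line" in d and isinstance(d["line"], Mapping):
            d["line"] = LineParams(**d["line"])
        if "gatne" in d and isinstance(d["gatne"], Mapping):
            g = dict(d["gatne"])
            if "meta_path" in g:
                g["meta_path"] = tuple(g["meta_path"])
            d["gatne"] = GatneConfig(**g)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        d = self.to_dict()
        d["gatne"]["meta_path"] = list(d["gatne"]["meta_path"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


def _hash_key(*parts) -> str:
    h = hashlib.sha256()
    for p in parts:
        h.update(json.dumps(p, sort_keys=True, default=str).encode())
    return h.hexdigest()[:24]


class PipelineRun:
    """One resolved run: loads inputs lazily, executes stages, writes artifacts."""

    def __init__(self, config: PipelineConfig, outdir: str | Path | None = None):
        self.config = config
        self.outdir = Path(outdir) if outdir is not None else None
        if self.outdir is not None:
            self.outdir.mkdir(parents=True, exist_ok=True)
            (self.outdir / "cache").mkdir(exist_ok=True)
        self._load_inputs()

    # ----------------------------------------------------------- stage 1: load

    def _load_inputs(self) -> None:
        cfg = self.config
        if cfg.fingerprints:
            self.sm_fps = read_fingerprint_sidecar(cfg.fingerprints)
        else:
            records = read_sm_table(cfg.sm_table)
            self.sm_fps, rejects = maccs_fingerprints(records)
            if rejects:
                logger.warning("dropped %d unparsable molecules", len(rejects))
        self.mirnas = {r.mirna_id: r for r in read_mirna_fasta(cfg.mirna_fasta)}
        edges = read_edge_list(cfg.edges).for_relation(cfg.relation)
        known_sm = set(self.sm_fps)
        known_mir = set(self.mirnas)
        dangling = [
            (e.sm_id, e.mirna_id)
            for e in edges
            if e.sm_id not in known_sm or e.mirna_id not in known_mir
        ]
        if dangling:
            raise ValidationError(f"edges reference unknown entities: {dangling[:5]}")
        if len(edges) == 0:
            raise ValidationError(f"no edges with relation {cfg.relation!r} in {cfg.edges}")
        self.positives = edges
        self.sm_ids = sorted(self.sm_fps)
        self.mirna_ids = sorted(self.mirnas)

    # ---------------------------------------------------------------- caching

    def _cached_embeddings(self, key: str, compute):
        """Compute-or-load an embedding table; always read back the cached file
        so fresh and cached runs see identical (6-decimal) values."""
        if self.outdir is None:
            path = None
        else:
            path = self.outdir / "cache" / f"{key}.w2v"
            if path.exists():
                logger.info("cache hit: %s", path.name)
                return read_embeddings(path)
        emb = compute()
        if path is not None:
            write_embeddings(emb, path)
            return read_embeddings(path)
        # no cache dir: round the same way for run-to-run consistency
        return {k: np.round(np.asarray(v), 6) for k, v in emb.items()}

    # -------------------------------------------------- stage 2: similarities

    def similarities(self) -> tuple[SimilarityMatrix, SimilarityMatrix]:
        sim_sm = similarity_matrix(self.sm_fps)
        mir_fps = {m: kmer_fingerprint(rec, self.config.kmer) for m, rec in self.mirnas.items()}
        sim_mir = similarity_matrix(mir_fps)
        return sim_sm, sim_mir

    def negatives(self, sim_sm: SimilarityMatrix) -> RegulationEdgeSet:
        cfg = self.config
        negs = sample_negatives(
            self.positives, sim_sm, self.sm_ids, self.mirna_ids,
            threshold=cfg.neg_threshold, seed=cfg.seed + 1,
        )
        if self.outdir is not None:
            write_edge_list(negs, self.outdir / f"negatives_{cfg.relation}.tsv")
        return negs

    # --------------------------------------------------- stage 3: attributes

    def attributes(self, sim_sm: SimilarityMatrix, sim_mir: SimilarityMatrix) -> dict[str, np.ndarray]:
        """Similarity-network embeddings as node attributes (namespaced ids)."""
        cfg = self.config
        lp = cfg.line

        def compute():
            attrs_sm = line_mod.line_attributes(
                sim_sm, dim=lp.dim, epochs=lp.epochs, negatives=lp.negatives,
                lr=lp.lr, seed=cfg.seed + 2, min_weight=lp.min_weight,
            )
            attrs_mir = line_mod.line_attributes(
                sim_mir, dim=lp.dim, epochs=lp.epochs, negatives=lp.negatives,
                lr=lp.lr, seed=cfg.seed + 3, min_weight=lp.min_weight,
            )
            out = {sm_vertex(k): v for k, v in attrs_sm.items()}
            out.update({mir_vertex(k): v for k, v in attrs_mir.items()})
            return out

        key = _hash_key(
            "attrs", asdict(lp), cfg.kmer, cfg.seed,
            sorted((k, sorted(v.bits)) for k, v in self.sm_fps.items()),
            sorted((m, r.sequence) for m, r in self.mirnas.items()),
        )
        return self._cached_embeddings(key, compute)

    def _onehot_attributes(self) -> dict[str, np.ndarray]:
        """One-hot identity attributes (structure-only ablation input)."""
        out: dict[str, np.ndarray] = {}
        for ids, ns in ((self.sm_ids, sm_vertex), (self.mirna_ids, mir_vertex)):
            n = len(ids)
            for i, k in enumerate(ids):
                v = np.zeros(n)
                v[i] = 1.0
                out[ns(k)] = v
        return out

    # ------------------------------------------------- stage 4+5: embed + CV

    def _embed_fn(self, attrs: dict[str, np.ndarray]):
        cfg = self.config

        def embed(train_pos: RegulationEdgeSet) -> Mapping[tuple[str, str], np.ndarray]:
            if cfg.mode == "attrs_only":
                return {(v, cfg.relation): x for v, x in attrs.items()}
            graph = build_multiplex_graph(train_pos, attrs)
            if cfg.mode == "transductive":
                return transductive_embed(graph, cfg.gatne, seed=cfg.seed + 5)
            return inductive_embed(graph, cfg.gatne, seed=cfg.seed + 5)

        return embed

    def _mode_attributes(self, sim_sm, sim_mir) -> dict[str, np.ndarray]:
        if self.config.mode == "gatne_only":
            return self._onehot_attributes()
        if self.config.mode == "transductive":
            # attributes are ignored by construction; keep a minimal placeholder
            return {v: np.ones(1) for v in
                    [sm_vertex(s) for s in self.sm_ids] + [mir_vertex(m) for m in self.mirna_ids]}
        return self.attributes(sim_sm, sim_mir)

    def cross_validate(self, shuffle_labels: bool = False) -> CvReport:
        cfg = self.config
        sim_sm, sim_mir = self.similarities()
        negs = self.negatives(sim_sm)
        attrs = self._mode_attributes(sim_sm, sim_mir)
        pairs = [(e.sm_id, e.mirna_id, 1) for e in self.positives] + [
            (e.sm_id, e.mirna_id, 0) for e in negs
        ]
        if shuffle_labels:
            labels = np.array([p[2] for p in pairs])
            rng = np.random.default_rng(cfg.seed + 99)
            rng.shuffle(labels)
            pairs = [(s, m, int(l)) for (s, m, _), l in zip(pairs, labels)]
        return cross_validate(
            pairs, cfg.relation, self._embed_fn(attrs), k=cfg.folds, seed=cfg.seed + 4,
            classifier=cfg.classifier, classifier_params=cfg.classifier_params,
            threshold=cfg.call_threshold,
        )

    def final_model(self, exclude_sm: str | None = None):
        """Train embeddings and classifier on all pairs (optionally holding out
        every pair of one SM, for candidate ranking)."""
        cfg = self.config
        sim_sm, sim_mir = self.similarities()
        negs = self.negatives(sim_sm)
        attrs = self._mode_attributes(sim_sm, sim_mir)
        positives = self.positives
        if exclude_sm is not None:
            positives = RegulationEdgeSet([e for e in positives if e.sm_id != exclude_sm])
        pairs = [(e.sm_id, e.mirna_id, 1) for e in positives] + [
            (e.sm_id, e.mirna_id, 0) for e in negs
            if exclude_sm is None or e.sm_id != exclude_sm
        ]
        emb = self._embed_fn(attrs)(RegulationEdgeSet(list(positives)))
        table = pair_features(emb, pairs, cfg.relation)
        model = fit_classifier(table, classifier=cfg.classifier, seed=cfg.seed,
                               params=cfg.classifier_params)
        return model, emb


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> CvReport:
    """Execute all stages; write report, embeddings, predictions and the
    resolved config when an output directory is given."""
    run = PipelineRun(config, outdir)
    report = run.cross_validate()
    if outdir is not None:
        outdir = Path(outdir)
        payload = {"config": config.to_dict(), "report": report.to_dict()}
        payload["config"]["gatne"]["meta_path"] = list(config.gatne.meta_path)
        with open(outdir / "report.json", "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")
        with open(outdir / "curves.csv", "w") as fh:
            fh.write("fold,curve,x,y\n")
            for row in report.curve_rows():
                fh.write("%d,%s,%.6f,%.6f\n" % row)
        config.to_yaml(outdir / "resolved_config.yaml")
        model, emb = run.final_model()
        write_embeddings({f"{v}@{r}": x for (v, r), x in emb.items()},
                         outdir / f"embeddings_{config.relation}.w2v")
        # score every labelled pair with the final model
        sim_sm, _ = run.similarities()
        negs = run.negatives(sim_sm)
        pairs = [(e.sm_id, e.mirna_id, 1) for e in run.positives] + [
            (e.sm_id, e.mirna_id, 0) for e in negs
        ]
        table = pair_features(emb, pairs, config.relation)
        scores = model.predict_proba(table.X)[:, 1]
        with open(outdir / "predictions.tsv", "w") as fh:
            fh.write("sm_id\tmirna_id\tlabel\tscore\n")
            for (s, m), label, sc in zip(table.pairs, table.y, scores):
                fh.write(f"{s}\t{m}\t{label}\t{sc:.6f}\n")
        with open(outdir / "run.log", "w") as fh:
            fh.write(f"relation={config.relation} mode={config.mode} seed={config.seed}\n")
            fh.write(f"n_positives={len(run.positives)} n_negatives={len(negs)}\n")
            for metric in report.METRICS:
                fh.write(f"{metric} {report.mean(metric):.4f} +/- {report.sd(metric):.4f}\n")
    return report


def rank_candidates_for_sm(
    config: PipelineConfig, sm_id: str, top: int = 10
) -> list[tuple[str, float]]:
    """Hold out every known pair of one SM, retrain, and rank its candidate miRNAs.

    Mirrors the case-study protocol: the returned list contains the miRNAs
    the model most confidently predicts the SM to regulate (relation per
    config), excluding nothing — known pairs were removed before training.
    """
    run = PipelineRun(config)
    if sm_id not in run.sm_ids:
        raise ValidationError(f"unknown SM id {sm_id!r}")
    model, emb = run.final_model(exclude_sm=sm_id)
    return rank_candidates(model, emb, sm_id, run.mirna_ids, config.relation, top=top)


def run_sensitivity(
    config: PipelineConfig,
    base_dims: list[int],
    edge_dims: list[int],
    outdir: str | Path | None = None,
):
    """Mean-AUC grid over the base (d) and edge (s) embedding dimensions.

    Cells share every other setting and all seeds; failures are recorded as
    NaN and the sweep continues.
    """
    if not base_dims or not edge_dims:
        raise ValidationError("dimension grids must be non-empty")
    grid = np.full((len(base_dims), len(edge_dims)), np.nan)
    for i, d in enumerate(base_dims):
        for j, s in enumerate(edge_dims):
            cfg = replace(config, gatne=replace(config.gatne, dim=d, edge_dim=s))
            try:
                report = run_pipeline(cfg, outdir=None)
                grid[i, j] = report.mean("AUC")
            except Exception:  # noqa: BLE001 - record and continue per contract
                logger.exception("sweep cell (dim=%d, edge_dim=%d) failed", d, s)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "sensitivity.csv", "w") as fh:
            fh.write("base_dim," + ",".join(str(s) for s in edge_dims) + "\n")
            for i, d in enumerate(base_dims):
                fh.write(str(d) + "," + ",".join(f"{v:.6f}" for v in grid[i]) + "\n")
    return grid
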