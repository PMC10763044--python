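"""Seeded generator of fully synthetic SM–miRNA regulation studies.

The generator plants recoverable structure at every level the pipeline
exploits:

* small molecules fall into fingerprint blocks sharing a structural-key bit
  template (bits flipped independently at ``noise_rate``), and miRNAs fall
  into sequence blocks whose members are rotations of one tiled core motif
  (identical k-mer sets within a block), so both Tanimoto self-similarity
  networks cluster by block;
* every entity gets a latent regulatory-class vector near a class centroid
  and positive regulation edges are drawn per relation without replacement
  with probability proportional to sigma(z_SM . z_miRNA). The SM's class is
  its fingerprint block — chemical structure is predictive of regulatory
  behaviour — while the miRNA's class is independent of its sequence block:
  sequence similarity alone does not reveal which chemicals regulate a
  miRNA, so recovering held-out links requires the network structure, as in
  real regulation data.

A ``null_model`` switch decouples the latent vectors from the blocks and
draws edges uniformly, providing a negative control in which no method
should beat chance.

All outputs are deterministic functions of the configuration (including its
seed). ``write_study`` emits plain-text files (TSV/FASTA/JSON) plus a
pre-computed fingerprint sidecar so the chemistry toolkit is not needed to
consume a study; the SMILES column holds a synthetic placeholder.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .exceptions import ValidationError
from .io_network import (
    MiRNARecord,
    RegulationEdge,
    RegulationEdgeSet,
    write_edge_list,
)
from .similarity import MACCS_BITS, Fingerprint

_BASES = "ACGU"
RELATIONS = ("up", "down")


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the planted synthetic benchmark."""

    n_sm: int = 60
    n_mirna: int = 40
    latent_dim: int = 4
    n_edges_per_relation: int = 400
    fingerprint_block_count: int = 4
    noise_rate: float = 0.05
    k: int = 4
    seed: int = 7
    null_model: bool = False

    def __post_init__(self):
        if not 0.0 <= self.noise_rate <= 1.0:
            raise ValidationError(f"noise_rate must be in [0, 1], got {self.noise_rate}")
        if self.n_edges_per_relation > self.n_sm * self.n_mirna:
            raise ValidationError("requested more edges than the bipartite capacity")
        if self.latent_dim < 1:
            raise ValidationError("latent_dim must be >= 1")


def _rng(cfg: SyntheticConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, stream])


def _blocks(cfg: SyntheticConfig) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic block assignment for SMs and miRNAs (round-robin)."""
    b = cfg.fingerprint_block_count
    return np.arange(cfg.n_sm) % b, np.arange(cfg.n_mirna) % b


def sm_ids(cfg: SyntheticConfig) -> list[str]:
    return [f"SM{i:04d}" for i in range(cfg.n_sm)]


def mirna_ids(cfg: SyntheticConfig) -> list[str]:
    return [f"syn-miR-{i:03d}" for i in range(cfg.n_mirna)]


def generate_fingerprints(
    cfg: SyntheticConfig,
) -> tuple[dict[str, Fingerprint], dict[str, MiRNARecord]]:
    """Block-structured SM structural keys and motif-tiled miRNA sequences."""
    b = cfg.fingerprint_block_count
    sm_block, mir_block = _blocks(cfg)
    rng = _rng(cfg, 1)
    # disjoint bit templates, ~60% of each block's bit range set
    span = MACCS_BITS // b
    templates = []
    for blk in range(b):
        lo = blk * span
        n_on = max(1, int(0.6 * span))
        bits = lo + rng.permutation(span)[:n_on]
        templates.append(np.zeros(MACCS_BITS, dtype=bool))
        templates[-1][bits] = True
    fps: dict[str, Fingerprint] = {}
    for i, sid in enumerate(sm_ids(cfg)):
        vec = templates[sm_block[i]].copy()
        flips = rng.random(MACCS_BITS) < cfg.noise_rate
        vec ^= flips
        if not vec.any():
            vec[sm_block[i] * span] = True  # keep fingerprints non-empty
        fps[sid] = Fingerprint(bits=frozenset(np.where(vec)[0].tolist()), length=MACCS_BITS)
    # miRNA sequences: rotations of a block-specific 8-mer core tiled to length
    # 22; every rotation contains all cyclic k-mers of the core, so within-block
    # k-mer fingerprints are identical and attributes carry the block only
    rng2 = _rng(cfg, 2)
    cores = ["".join(_BASES[j] for j in rng2.integers(0, 4, size=8)) for _ in range(b)]
    mirnas: dict[str, MiRNARecord] = {}
    for i, mid in enumerate(mirna_ids(cfg)):
        core = cores[mir_block[i]]
        offset = (i // b) % len(core)
        seq = ((core + core)[offset:] * 4)[:22]
        mirnas[mid] = MiRNARecord(mirna_id=mid, sequence=seq)
    return fps, mirnas


def mirna_classes(cfg: SyntheticConfig) -> np.ndarray:
    """Latent regulatory class per miRNA, independent of its sequence block."""
    return _rng(cfg, 5).integers(0, cfg.fingerprint_block_count, size=cfg.n_mirna)


def _latents(cfg: SyntheticConfig, relation: str) -> tuple[np.ndarray, np.ndarray]:
    """Per-entity latent vectors for one relation layer.

    SM latents sit near their fingerprint block's class centroid; miRNA
    latents near their (sequence-independent) regulatory class centroid.
    """
    sm_block, _ = _blocks(cfg)
    stream = 10 + RELATIONS.index(relation)
    rng = _rng(cfg, stream)
    b = cfg.fingerprint_block_count
    if cfg.null_model:
        z_sm = rng.normal(size=(cfg.n_sm, cfg.latent_dim))
        z_mir = rng.normal(size=(cfg.n_mirna, cfg.latent_dim))
        return z_sm, z_mir
    mir_cls = mirna_classes(cfg)
    centroids_sm = rng.normal(size=(b, cfg.latent_dim))
    centroids_mir = rng.normal(size=(b, cfg.latent_dim))
    z_sm = centroids_sm[sm_block] + 0.15 * rng.normal(size=(cfg.n_sm, cfg.latent_dim))
    z_mir = centroids_mir[mir_cls] + 0.15 * rng.normal(size=(cfg.n_mirna, cfg.latent_dim))
    return z_sm, z_mir


def edge_weights(cfg: SyntheticConfig, relation: str) -> np.ndarray:
    """Unnormalised selection weight sigma(z_SM . z_miRNA) for every pair."""
    z_sm, z_mir = _latents(cfg, relation)
    dots = z_sm @ z_mir.T
    if cfg.null_model:
        return np.ones_like(dots)
    return 1.0 / (1.0 + np.exp(-2.0 * dots))


def generate_edges(cfg: SyntheticConfig, relation: str | None = None) -> RegulationEdgeSet:
    """Planted positive edges, sampled without replacement with affinity weights."""
    relations = RELATIONS if relation is None else (relation,)
    sids, mids = sm_ids(cfg), mirna_ids(cfg)
    edges: list[RegulationEdge] = []
    for rel in relations:
        w = edge_weights(cfg, rel).ravel()
        rng = _rng(cfg, 20 + RELATIONS.index(rel))
        chosen = rng.choice(w.size, size=cfg.n_edges_per_relation, replace=False, p=w / w.sum())
        for flat in sorted(chosen.tolist()):
            si, mi = divmod(flat, cfg.n_mirna)
            edges.append(RegulationEdge(sids[si], mids[mi], rel))
    return RegulationEdgeSet(edges)


def write_fingerprint_sidecar(fps: dict[str, Fingerprint], path: str | Path) -> None:
    """TSV sidecar: sm_id, fingerprint length, comma-joined set-bit indices."""
    with open(path, "w") as fh:
        fh.write("sm_id\tlength\tbits\n")
        for sid in sorted(fps):
            fp = fps[sid]
            fh.write(f"{sid}\t{fp.length}\t{','.join(map(str, sorted(fp.bits)))}\n")


def read_fingerprint_sidecar(path: str | Path) -> dict[str, Fingerprint]:
    fps: dict[str, Fingerprint] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["sm_id", "length", "bits"]:
            raise ValidationError(f"{path}: not a fingerprint sidecar")
        for line in fh:
            sid, length, bits = line.rstrip("\n").split("\t")
            idx = frozenset(int(b) for b in bits.split(",") if b != "")
            fps[sid] = Fingerprint(bits=idx, length=int(length))
    return fps


def write_study(cfg: SyntheticConfig, outdir: str | Path) -> dict[str, Path]:
    """Emit the study as plain-text files; byte-identical for identical configs.

    The smiles column carries a synthetic placeholder ("C"); consumers use
    the fingerprint sidecar instead of re-deriving keys from chemistry.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fps, mirnas = generate_fingerprints(cfg)
    edges = generate_edges(cfg)
    paths = {
        "sm": outdir / "sm.tsv",
        "fingerprints": outdir / "sm_fingerprints.tsv",
        "mirna": outdir / "mirna.fasta",
        "edges_up": outdir / "edges_up.tsv",
        "edges_down": outdir / "edges_down.tsv",
        "truth": outdir / "truth.json",
    }
    with open(paths["sm"], "w") as fh:
        fh.write("sm_id\tsmiles\n")
        for sid in sm_ids(cfg):
            fh.write(f"{sid}\tC\n")
    write_fingerprint_sidecar(fps, paths["fingerprints"])
    with open(paths["mirna"], "w") as fh:
        for mid in mirna_ids(cfg):
            fh.write(f">{mid}\n{mirnas[mid].sequence}\n")
    write_edge_list(edges.for_relation("up"), paths["edges_up"])
    write_edge_list(edges.for_relation("down"), paths["edges_down"])
    sm_block, mir_block = _blocks(cfg)
    truth = {
        "config": asdict(cfg),
        "sm_blocks": {s: int(b) for s, b in zip(sm_ids(cfg), sm_block)},
        "mirna_blocks": {m: int(b) for m, b in zip(mirna_ids(cfg), mir_block)},
        "mirna_classes": {m: int(c) for m, c in zip(mirna_ids(cfg), mirna_classes(cfg))},
        "planted_edges": [[e.sm_id, e.mirna_id, e.relation] for e in edges],
    }
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return paths
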