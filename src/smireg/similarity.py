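"""Fingerprints, Tanimoto self-similarity networks and negative sampling.

Small molecules are represented by the 166 public MACCS structural keys;
miRNAs by binary k-mer presence vectors over their U-normalised sequence
(default k = 4, the natural sequence analogue of structural keys). Pairwise
Tanimoto coefficients |A∩B| / |A∪B| over these binary fingerprints define
the two self-similarity networks.

Negative (non-regulating) pairs are drawn from the unlabelled SM–miRNA
pairs whose regulation-proximity score — the mean Tanimoto similarity of
the candidate SM to the miRNAs' known regulators within the same relation
layer — falls strictly below a threshold (default 0.1). Pairs whose miRNA
has no known regulator in the layer are unscorable and excluded from the
pool.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np

from .exceptions import ValidationError
from .io_network import (
    MiRNARecord,
    RegulationEdge,
    RegulationEdgeSet,
    SmallMoleculeRecord,
)

logger = logging.getLogger(__name__)

MACCS_BITS = 166

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "U": 3}


@dataclass(frozen=True)
class Fingerprint:
    """Binary fingerprint as a set of set-bit indices over a fixed length."""

    bits: frozenset[int]
    length: int

    def __post_init__(self):
        if self.length <= 0:
            raise ValidationError("fingerprint length must be positive")
        bad = [b for b in self.bits if not (0 <= b < self.length)]
        if bad:
            raise ValidationError(f"bit indices out of range [0, {self.length}): {sorted(bad)}")


@dataclass
class SimilarityMatrix:
    """Symmetric Tanimoto similarity matrix over an ordered id list."""

    ids: list[str]
    S: np.ndarray

    def __post_init__(self):
        self._index = {v: i for i, v in enumerate(self.ids)}

    def value(self, a: str, b: str) -> float:
        return float(self.S[self._index[a], self._index[b]])

    def __contains__(self, key: str) -> bool:
        return key in self._index


@dataclass(frozen=True)
class RegulationScore:
    sm_id: str
    mirna_id: str
    score: float


def maccs_fingerprint(record: SmallMoleculeRecord) -> Optional[Fingerprint]:
    """MACCS structural-key fingerprint of a SMILES; None if unparsable.

    RDKit's MACCS implementation uses 167 bits with bit 0 unused; indices are
    shifted down by one so the result spans exactly the 166 public keys.
    """
    from rdkit import Chem, RDLogger
    from rdkit.Chem import MACCSkeys

    RDLogger.DisableLog("rdApp.error")
    mol = Chem.MolFromSmiles(record.smiles)
    if mol is None:
        return None
    keys = MACCSkeys.GenMACCSKeys(mol)
    bits = frozenset(b - 1 for b in keys.GetOnBits())
    return Fingerprint(bits=bits, length=MACCS_BITS)


def maccs_fingerprints(
    records: list[SmallMoleculeRecord],
) -> tuple[dict[str, Fingerprint], list[SmallMoleculeRecord]]:
    """Batch MACCS fingerprints; unparsable molecules go to a rejects list."""
    fps: dict[str, Fingerprint] = {}
    rejects: list[SmallMoleculeRecord] = []
    for rec in records:
        fp = maccs_fingerprint(rec)
        if fp is None or not fp.bits:
            logger.warning("dropping molecule %s: unparsable or empty SMILES %r", rec.sm_id, rec.smiles)
            rejects.append(rec)
        else:
            fps[rec.sm_id] = fp
    return fps, rejects


def kmer_fingerprint(record: MiRNARecord, k: int = 4) -> Fingerprint:
    """Binary k-mer presence fingerprint over the 4^k possible k-mers."""
    if k < 1:
        raise ValidationError(f"k must be >= 1, got {k}")
    seq = record.sequence
    if len(seq) < k:
        raise ValidationError(
            f"sequence of {record.mirna_id} has length {len(seq)} < k = {k}"
        )
    bits = set()
    for start in range(len(seq) - k + 1):
        idx = 0
        for ch in seq[start : start + k]:
            idx = idx * 4 + _BASE_INDEX[ch]
        bits.add(idx)
    return Fingerprint(bits=frozenset(bits), length=4 ** k)


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto coefficient |A∩B| / |A∪B|; 0.0 when both fingerprints are empty."""
    if a.length != b.length:
        raise ValidationError(f"fingerprint length mismatch: {a.length} vs {b.length}")
    union = len(a.bits | b.bits)
    if union == 0:
        return 0.0
    return len(a.bits & b.bits) / union


def similarity_matrix(fps: Mapping[str, Fingerprint]) -> SimilarityMatrix:
    """Full symmetric pairwise-Tanimoto matrix, rows ordered by sorted id."""
    if len(fps) < 2:
        raise ValidationError("need at least 2 fingerprints")
    lengths = {fp.length for fp in fps.values()}
    if len(lengths) > 1:
        raise ValidationError(f"mixed fingerprint lengths: {sorted(lengths)}")
    ids = sorted(fps)
    n = len(ids)
    S = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            S[i, j] = S[j, i] = tanimoto(fps[ids[i]], fps[ids[j]])
    return SimilarityMatrix(ids=ids, S=S)


def regulation_score(
    sm_id: str,
    mirna_id: str,
    positives: RegulationEdgeSet,
    sim: SimilarityMatrix,
) -> Optional[RegulationScore]:
    """Mean Tanimoto similarity of the SM to the miRNA's known regulators.

    ``positives`` must already be restricted to one relation layer. Returns
    None (unscorable) when the miRNA has no known regulator in the layer.
    """
    regulators = sorted({e.sm_id for e in positives if e.mirna_id == mirna_id})
    if not regulators:
        return None
    vals = [sim.value(sm_id, r) for r in regulators]
    return RegulationScore(sm_id=sm_id, mirna_id=mirna_id, score=float(np.mean(vals)))


def negative_pool(
    positives: RegulationEdgeSet,
    sim: SimilarityMatrix,
    sm_ids: list[str],
    mirna_ids: list[str],
    threshold: float = 0.1,
) -> list[tuple[str, str]]:
    """All unlabelled (sm, mirna) pairs with regulation score strictly below threshold.

    The eligible set is enumerated exhaustively over the full SM × miRNA grid;
    positives and unscorable pairs (miRNA with no known regulator) are excluded.
    """
    if len({e.relation for e in positives}) > 1:
        raise ValidationError("positives must be restricted to a single relation layer")
    pos_pairs = positives.pairs()
    regulators: dict[str, list[str]] = {}
    for e in positives:
        regulators.setdefault(e.mirna_id, []).append(e.sm_id)
    pool: list[tuple[str, str]] = []
    for m in sorted(mirna_ids):
        regs = sorted(set(regulators.get(m, [])))
        if not regs:
            continue
        for s in sorted(sm_ids):
            if (s, m) in pos_pairs:
                continue
            score = float(np.mean([sim.value(s, r) for r in regs]))
            if score < threshold:
                pool.append((s, m))
    return pool


def sample_negatives(
    positives: RegulationEdgeSet,
    sim: SimilarityMatrix,
    sm_ids: list[str],
    mirna_ids: list[str],
    threshold: float = 0.1,
    n: int | None = None,
    seed: int = 0,
) -> RegulationEdgeSet:
    """Draw n negatives uniformly without replacement from the eligible pool.

    Defaults to a balanced draw (n = |positives|). The pool is deterministic
    (sorted enumeration) and the draw is reproducible from the seed.
    """
    if len(positives) == 0:
        raise ValidationError("positives must be non-empty")
    relations = positives.relations()
    if len(relations) != 1:
        raise ValidationError(
            f"sample_negatives operates on one relation layer, got {relations}"
        )
    relation = relations[0]
    if n is None:
        n = len(positives)
    pool = negative_pool(positives, sim, sm_ids, mirna_ids, threshold)
    if len(pool) < n:
        raise ValidationError(
            f"negative pool has only {len(pool)} eligible pairs, need {n}"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pool), size=n, replace=False)
    logger.info(
        "sampled %d negatives for relation %r from pool of %d (threshold %.3g, seed %d)",
        n, relation, len(pool), threshold, seed,
    )
    chosen = [pool[i] for i in sorted(idx)]
    return RegulationEdgeSet([RegulationEdge(s, m, relation) for s, m in chosen])
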