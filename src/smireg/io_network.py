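"""Readers/writers for the external formats and the attributed multiplex graph.

File formats are deliberately plain text: tab-separated tables with a header
row for small molecules and regulation edges, FASTA for miRNA sequences and
the word2vec text format for embedding tables, so every artifact can be
inspected and diffed.

Vertex ids are namespaced internally ("sm:" / "mir:" prefixes) so a small
molecule and a miRNA sharing a raw identifier can never collide; external
files always carry the raw ids.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

from .exceptions import FormatError, ValidationError

logger = logging.getLogger(__name__)

SM_PREFIX = "sm:"
MIR_PREFIX = "mir:"

_RNA_ALPHABET = frozenset("ACGU")


def sm_vertex(sm_id: str) -> str:
    """Namespace a raw small-molecule id into a graph vertex id."""
    return SM_PREFIX + sm_id


def mir_vertex(mirna_id: str) -> str:
    """Namespace a raw miRNA id into a graph vertex id."""
    return MIR_PREFIX + mirna_id


def raw_id(vertex: str) -> str:
    """Strip the namespace prefix from a vertex id."""
    for prefix in (SM_PREFIX, MIR_PREFIX):
        if vertex.startswith(prefix):
            return vertex[len(prefix):]
    return vertex


def vertex_type(vertex: str) -> str:
    """Node type ('sm' or 'mir') of a namespaced vertex id."""
    if vertex.startswith(SM_PREFIX):
        return "sm"
    if vertex.startswith(MIR_PREFIX):
        return "mir"
    raise ValidationError(f"vertex id {vertex!r} carries no recognised namespace prefix")


@dataclass(frozen=True)
class SmallMoleculeRecord:
    sm_id: str
    smiles: str


@dataclass(frozen=True)
class MiRNARecord:
    mirna_id: str
    sequence: str  # uppercase, U-normalised


@dataclass(frozen=True)
class RegulationEdge:
    sm_id: str
    mirna_id: str
    relation: str  # 'up' or 'down'


@dataclass
class RegulationEdgeSet:
    """De-duplicated set of (sm, mirna, relation) triples, order preserved."""

    edges: list[RegulationEdge] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.edges)

    def __iter__(self):
        return iter(self.edges)

    def __contains__(self, edge: RegulationEdge) -> bool:
        return edge in set(self.edges)

    def relations(self) -> list[str]:
        seen: dict[str, None] = {}
        for e in self.edges:
            seen.setdefault(e.relation, None)
        return list(seen)

    def for_relation(self, relation: str) -> "RegulationEdgeSet":
        return RegulationEdgeSet([e for e in self.edges if e.relation == relation])

    def pairs(self) -> set[tuple[str, str]]:
        return {(e.sm_id, e.mirna_id) for e in self.edges}

    def sm_ids(self) -> list[str]:
        return sorted({e.sm_id for e in self.edges})

    def mirna_ids(self) -> list[str]:
        return sorted({e.mirna_id for e in self.edges})


VALID_RELATIONS = ("up", "down")


def read_sm_table(path: str | Path) -> list[SmallMoleculeRecord]:
    """Read a TSV of small molecules with columns ``sm_id`` and ``smiles``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sm_id", "smiles"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    records = []
    for _, row in df.iterrows():
        sm_id = "" if pd.isna(row["sm_id"]) else str(row["sm_id"]).strip()
        smiles = "" if pd.isna(row["smiles"]) else str(row["smiles"]).strip()
        if not sm_id:
            raise ValidationError(f"{path}: row with empty sm_id")
        if not smiles:
            raise ValidationError(f"{path}: empty smiles for sm_id {sm_id!r}")
        records.append(SmallMoleculeRecord(sm_id=sm_id, smiles=smiles))
    ids = [r.sm_id for r in records]
    dupes = sorted({i for i in ids if ids.count(i) > 1})
    if dupes:
        raise ValidationError(f"{path}: duplicate sm_id values: {dupes}")
    return records


def read_mirna_fasta(path: str | Path) -> list[MiRNARecord]:
    """Read miRNA sequences from FASTA; sequences are uppercased and T→U normalised."""
    records: list[MiRNARecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        mirna_id = rec.id
        if mirna_id in seen:
            raise ValidationError(f"{path}: duplicate miRNA id {mirna_id!r}")
        seen.add(mirna_id)
        seq = str(rec.seq).upper().replace("T", "U")
        for pos, ch in enumerate(seq, start=1):
            if ch not in _RNA_ALPHABET:
                raise ValidationError(
                    f"{path}: invalid character {ch!r} at position {pos} of {mirna_id}"
                )
        records.append(MiRNARecord(mirna_id=mirna_id, sequence=seq))
    return records


def read_edge_list(path: str | Path) -> RegulationEdgeSet:
    """Read a regulation edge TSV with columns sm_id, mirna_id, relation.

    Relation tokens are lower-cased; exact duplicate triples are collapsed with
    a logged warning.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sm_id", "mirna_id", "relation"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    edges: list[RegulationEdge] = []
    seen: set[RegulationEdge] = set()
    n_dupes = 0
    for _, row in df.iterrows():
        relation = str(row["relation"]).strip().lower()
        if relation not in VALID_RELATIONS:
            raise FormatError(
                f"{path}: unknown relation token {row['relation']!r} "
                f"(expected one of {VALID_RELATIONS})"
            )
        edge = RegulationEdge(str(row["sm_id"]).strip(), str(row["mirna_id"]).strip(), relation)
        if edge in seen:
            n_dupes += 1
            continue
        seen.add(edge)
        edges.append(edge)
    if n_dupes:
        logger.warning("%s: collapsed %d duplicate edge rows", path, n_dupes)
    return RegulationEdgeSet(edges)


def write_edge_list(edges: RegulationEdgeSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sm_id\tmirna_id\trelation\n")
        for e in edges:
            fh.write(f"{e.sm_id}\t{e.mirna_id}\t{e.relation}\n")


class MultiplexGraph:
    """Attributed multiplex heterogeneous graph over SM and miRNA vertices.

    Each relation layer is an undirected bipartite edge set between the two
    node types; every vertex carries an attribute vector (dimensionality may
    differ between the two types but is uniform within a type).
    """

    def __init__(
        self,
        edges_by_relation: Mapping[str, Iterable[tuple[str, str]]],
        attributes: Mapping[str, np.ndarray],
    ):
        self.attributes = {v: np.asarray(x, dtype=float) for v, x in attributes.items()}
        self._adj: dict[str, dict[str, list[str]]] = {}
        vertices: set[str] = set()
        missing: set[str] = set()
        for relation, pairs in edges_by_relation.items():
            adj: dict[str, set[str]] = {}
            for u, v in pairs:
                tu, tv = vertex_type(u), vertex_type(v)
                if {tu, tv} != {"sm", "mir"}:
                    raise ValidationError(
                        f"layer {relation!r}: edge ({u}, {v}) is not SM–miRNA bipartite"
                    )
                for w in (u, v):
                    if w not in self.attributes:
                        missing.add(w)
                adj.setdefault(u, set()).add(v)
                adj.setdefault(v, set()).add(u)
                vertices.update((u, v))
            self._adj[relation] = {w: sorted(nb) for w, nb in adj.items()}
        if missing:
            raise ValidationError(f"vertices without attribute vectors: {sorted(missing)}")
        # include attribute-only vertices so they can still be embedded
        vertices.update(self.attributes)
        self.vertices: list[str] = sorted(vertices)
        dims: dict[str, set[int]] = {}
        for v, x in self.attributes.items():
            dims.setdefault(vertex_type(v), set()).add(x.shape[0])
        for z, ds in dims.items():
            if len(ds) > 1:
                raise ValidationError(f"inconsistent attribute dimensions for type {z!r}: {sorted(ds)}")

    @property
    def relations(self) -> list[str]:
        return sorted(self._adj)

    def neighbors(self, vertex: str, relation: str) -> list[str]:
        return self._adj[relation].get(vertex, [])

    def edges(self, relation: str) -> list[tuple[str, str]]:
        out = []
        for u, nbrs in self._adj[relation].items():
            for v in nbrs:
                if u < v:
                    out.append((u, v))
        return sorted(out)

    def node_type(self, vertex: str) -> str:
        return vertex_type(vertex)

    def attribute_dim(self, node_type: str) -> int:
        for v, x in self.attributes.items():
            if vertex_type(v) == node_type:
                return x.shape[0]
        raise ValidationError(f"no vertices of type {node_type!r}")


def build_multiplex_graph(
    edges: RegulationEdgeSet, attributes: Mapping[str, np.ndarray]
) -> MultiplexGraph:
    """Assemble the multiplex graph: one undirected bipartite layer per relation.

    Raw edge ids are namespaced; every endpoint must have an attribute vector.
    Deterministic and insensitive to input edge ordering.
    """
    layers: dict[str, list[tuple[str, str]]] = {}
    for e in edges:
        layers.setdefault(e.relation, []).append((sm_vertex(e.sm_id), mir_vertex(e.mirna_id)))
    return MultiplexGraph(layers, attributes)


def write_embeddings(emb: Mapping[str, np.ndarray], path: str | Path) -> None:
    """Write an embedding table in word2vec text format ("N d" header)."""
    keys = sorted(emb)
    if not keys:
        raise ValidationError("empty embedding table")
    dims = {np.asarray(emb[k]).shape[0] for k in keys}
    if len(dims) > 1:
        raise ValidationError(f"ragged embedding vectors: dims {sorted(dims)}")
    d = dims.pop()
    with open(path, "w") as fh:
        fh.write(f"{len(keys)} {d}\n")
        for k in keys:
            vec = " ".join(f"{x:.6f}" for x in np.asarray(emb[k], dtype=float))
            fh.write(f"{k} {vec}\n")


def read_embeddings(path: str | Path) -> dict[str, np.ndarray]:
    """Read a word2vec text format embedding table."""
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise FormatError(f"{path}: malformed word2vec header")
        n, d = int(header[0]), int(header[1])
        emb: dict[str, np.ndarray] = {}
        for line in fh:
            parts = line.rstrip("\n").split(" ")
            if len(parts) != d + 1:
                raise FormatError(f"{path}: row with {len(parts) - 1} values, expected {d}")
            emb[parts[0]] = np.array([float(x) for x in parts[1:]])
    if len(emb) != n:
        raise FormatError(f"{path}: header claims {n} rows, found {len(emb)}")
    return emb
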