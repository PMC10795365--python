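"""Reading, writing and synthesis of association tables and disease ontologies.

The two on-disk formats are deliberately minimal, headerless TSV:

* associations: two columns ``(lncrna_id, disease_id)``, one validated pair
  per line;
* ontology: two columns ``(child_term, parent_term)`` plus a two-column
  mapping file ``(disease_id, term)``.

Identifier order is lexicographic after deduplication and every downstream
matrix inherits it, so row *i* / column *j* mean the same entity everywhere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np

__all__ = [
    "AssociationDataset",
    "DiseaseOntology",
    "SyntheticSpec",
    "read_associations",
    "write_associations",
    "read_ontology",
    "write_ontology",
    "generate_synthetic",
    "shuffle_associations",
]


@dataclass
class AssociationDataset:
    """A binary lncRNA x disease association matrix with its identifiers."""

    lncrna_ids: list[str]
    disease_ids: list[str]
    A: np.ndarray

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A)
        if self.A.shape != (len(self.lncrna_ids), len(self.disease_ids)):
            raise ValueError(
                f"matrix shape {self.A.shape} does not match "
                f"{len(self.lncrna_ids)} lncRNAs x {len(self.disease_ids)} diseases"
            )
        if len(set(self.lncrna_ids)) != len(self.lncrna_ids):
            raise ValueError("duplicate lncRNA identifiers")
        if len(set(self.disease_ids)) != len(self.disease_ids):
            raise ValueError("duplicate disease identifiers")
        if not np.isin(self.A, (0, 1)).all():
            raise ValueError("association matrix entries must be 0 or 1")
        self.A = self.A.astype(np.int8)

    @property
    def n_lnc(self) -> int:
        return len(self.lncrna_ids)

    @property
    def n_dis(self) -> int:
        return len(self.disease_ids)

    def positives(self) -> np.ndarray:
        """(n_pos, 2) array of (row, col) indices of validated associations."""
        return np.argwhere(self.A == 1)

    def masked(self, pairs: np.ndarray) -> "AssociationDataset":
        """Copy with the given (row, col) entries forced to 0 (held-out fold)."""
        A = self.A.copy()
        pairs = np.asarray(pairs)
        if len(pairs):
            A[pairs[:, 0], pairs[:, 1]] = 0
        return AssociationDataset(list(self.lncrna_ids), list(self.disease_ids), A)

    @classmethod
    def from_pairs(
        cls, pairs: Sequence[tuple[str, str]]
    ) -> "AssociationDataset":
        lnc = sorted({p[0] for p in pairs})
        dis = sorted({p[1] for p in pairs})
        li = {v: i for i, v in enumerate(lnc)}
        di = {v: i for i, v in enumerate(dis)}
        A = np.zeros((len(lnc), len(dis)), dtype=np.int8)
        for l, d in pairs:
            A[li[l], di[d]] = 1
        return cls(lnc, dis, A)


def read_associations(path: str | Path) -> AssociationDataset:
    """Parse a two-column (lncrna_id, disease_id) TSV edge list."""
    pairs: list[tuple[str, str]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 2 or not fields[0] or not fields[1]:
                raise ValueError(
                    f"{path}: line {lineno}: expected two tab-separated fields, "
                    f"got {line!r}"
                )
            pairs.append((fields[0], fields[1]))
    if not pairs:
        raise ValueError(f"{path}: no association pairs found")
    return AssociationDataset.from_pairs(pairs)


def write_associations(ds: AssociationDataset, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for i, j in ds.positives():
            fh.write(f"{ds.lncrna_ids[i]}\t{ds.disease_ids[j]}\n")


@dataclass
class DiseaseOntology:
    """A rooted DAG over disease terms plus a disease -> term mapping.

    Edges point parent -> child.  ``T(d)`` is the ancestor closure of the
    disease's term (the term itself plus everything reachable via parent
    links); ``E(d)`` is the induced edge set among ``T(d)``.
    """

    graph: nx.DiGraph
    mapping: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            edge = nx.find_cycle(self.graph)[0]
            raise ValueError(f"ontology contains a cycle through edge {edge[:2]}")
        for disease, term in self.mapping.items():
            if term not in self.graph:
                raise ValueError(
                    f"disease {disease!r} mapped to missing term {term!r}"
                )

    def term_of(self, disease: str) -> str:
        try:
            return self.mapping[disease]
        except KeyError:
            raise KeyError(f"disease {disease!r} has no ontology term") from None

    def ancestor_closure(self, disease: str) -> set[str]:
        """T(d): the disease's term plus all its ancestors."""
        term = self.term_of(disease)
        return {term} | nx.ancestors(self.graph, term)

    def edge_set(self, disease: str) -> set[tuple[str, str]]:
        """E(d): parent->child edges induced among T(d)."""
        closure = self.ancestor_closure(disease)
        return {
            (u, v) for u, v in self.graph.edges if u in closure and v in closure
        }


def read_ontology(
    edges_path: str | Path, mapping_path: str | Path
) -> DiseaseOntology:
    """Parse a (child_term, parent_term) TSV and a (disease_id, term) TSV."""
    g = nx.DiGraph()
    with open(edges_path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 2 or not fields[0] or not fields[1]:
                raise ValueError(
                    f"{edges_path}: line {lineno}: expected two tab-separated "
                    f"fields, got {line!r}"
                )
            child, parent = fields
            g.add_edge(parent, child)
    mapping: dict[str, str] = {}
    with open(mapping_path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(
                    f"{mapping_path}: line {lineno}: expected two tab-separated "
                    f"fields, got {line!r}"
                )
            mapping[fields[0]] = fields[1]
    return DiseaseOntology(g, mapping)


def write_ontology(
    onto: DiseaseOntology, edges_path: str | Path, mapping_path: str | Path
) -> None:
    with open(edges_path, "w", encoding="utf-8") as fh:
        for parent, child in sorted(onto.graph.edges):
            fh.write(f"{child}\t{parent}\n")
    with open(mapping_path, "w", encoding="utf-8") as fh:
        for disease in sorted(onto.mapping):
            fh.write(f"{disease}\t{onto.mapping[disease]}\n")


@dataclass
class SyntheticSpec:
    """Parameters of the planted-block benchmark generator.

    Entities are assigned to latent blocks round-robin and associations are
    Bernoulli draws: probability ``p_in`` when the lncRNA and the disease
    share a block, ``p_out`` otherwise.  The ontology is a random rooted
    tree whose per-block subtrees group the diseases of one block, so that
    semantic similarity correlates with block identity and held-out links
    are learnable from the remaining structure.
    """

    n_lnc: int = 60
    n_dis: int = 50
    n_blocks: int = 5
    p_in: float = 0.3
    p_out: float = 0.02
    dag_depth: int = 3
    dag_branching: int = 2
    seed: int = 1

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_out <= self.p_in <= 1.0):
            raise ValueError("require 0 <= p_out <= p_in <= 1")
        if min(self.n_lnc, self.n_dis, self.n_blocks) < 1:
            raise ValueError("sizes and block count must be positive")


def generate_synthetic(
    spec: SyntheticSpec,
) -> tuple[AssociationDataset, DiseaseOntology]:
    """Draw a planted-block association matrix and a block-aligned ontology."""
    rng = np.random.default_rng(spec.seed)
    lnc_ids = [f"l{i:04d}" for i in range(spec.n_lnc)]
    dis_ids = [f"d{j:04d}" for j in range(spec.n_dis)]
    lnc_block = np.arange(spec.n_lnc) % spec.n_blocks
    dis_block = np.arange(spec.n_dis) % spec.n_blocks
    same = lnc_block[:, None] == dis_block[None, :]
    prob = np.where(same, spec.p_in, spec.p_out)
    A = (rng.random((spec.n_lnc, spec.n_dis)) < prob).astype(np.int8)

    zero_rows = int((A.sum(axis=1) == 0).sum())
    zero_cols = int((A.sum(axis=0) == 0).sum())
    if zero_rows > spec.n_lnc / 2 or zero_cols > spec.n_dis / 2:
        warnings.warn(
            "synthetic dataset is very sparse: more than half of the rows or "
            "columns have no association; cross-validation may be unstable",
            stacklevel=2,
        )

    g = nx.DiGraph()
    root = "ROOT"
    g.add_node(root)
    mapping: dict[str, str] = {}
    for b in range(spec.n_blocks):
        block_root = f"B{b}"
        g.add_edge(root, block_root)
        # random internal tree under the block root
        internal = [block_root]
        for depth in range(1, spec.dag_depth):
            for k in range(spec.dag_branching):
                parent = internal[int(rng.integers(len(internal)))]
                node = f"B{b}_n{depth}_{k}"
                g.add_edge(parent, node)
                internal.append(node)
        for j in np.flatnonzero(dis_block == b):
            term = dis_ids[j]
            parent = internal[int(rng.integers(len(internal)))]
            g.add_edge(parent, term)
            mapping[dis_ids[j]] = term

    return (
        AssociationDataset(lnc_ids, dis_ids, A),
        DiseaseOntology(g, mapping),
    )


def shuffle_associations(
    ds: AssociationDataset, rng: np.random.Generator
) -> AssociationDataset:
    """Permute all matrix entries, destroying block structure but keeping density."""
    flat = ds.A.flatten()
    rng.shuffle(flat)
    return AssociationDataset(
        list(ds.lncrna_ids), list(ds.disease_ids), flat.reshape(ds.A.shape)
    )
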