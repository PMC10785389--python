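"""Shared domain types for the causal miRNA-disease association predictor.

The pipeline moves five kinds of objects between stages: per-miRNA feature
bundles (:class:`MirnaProfileSet`), square similarity matrices
(:class:`SimilarityMatrix`), the binary causal association matrix
(:class:`AssociationMatrix`), the disease term DAG (:class:`DiseaseDAG`)
and real-valued prediction matrices (:class:`ScoreMatrix`).  Every type
validates its own invariants on construction so that downstream stages can
assume well-formed inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np

__all__ = [
    "MirnaProfileSet",
    "AssociationMatrix",
    "SimilarityMatrix",
    "DiseaseDAG",
    "ScoreMatrix",
    "SIMILARITY_METRICS",
]

# canonical metric labels, in the fusion order used throughout
SIMILARITY_METRICS = ("seq", "expr", "gip", "pathway", "gene", "tf")

_VALID_METRICS = frozenset(SIMILARITY_METRICS) | {"disease_semantic"}

_RNA_COMPLETE = set("ACGUNRYSWKMBDHV")  # IUPAC nucleotide letters, RNA alphabet


def _check_unique(ids: Sequence[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        seen: set = set()
        dup = next(i for i in ids if i in seen or seen.add(i))
        raise ValueError(f"duplicate {what} identifier: {dup!r}")


def normalize_sequence(seq: str, name: str = "?") -> str:
    """Uppercase a nucleotide sequence and unify T -> U (RNA alphabet)."""
    s = seq.strip().upper().replace("T", "U")
    if not s:
        raise ValueError(f"empty sequence for {name!r}")
    bad = set(s) - _RNA_COMPLETE
    if bad:
        raise ValueError(f"non-IUPAC letters {sorted(bad)} in sequence for {name!r}")
    return s


@dataclass
class MirnaProfileSet:
    """Per-miRNA feature bundle.

    Feature blocks are optional: a block that is present must cover exactly
    the ids it declares (a subset of ``mirna_ids``); binary blocks hold only
    {0,1}; continuous blocks hold finite nonnegative reals.
    """

    mirna_ids: List[str]
    precursor_seq: Dict[str, str] = field(default_factory=dict)
    mature_seq: Dict[str, str] = field(default_factory=dict)
    seed_seq: Dict[str, str] = field(default_factory=dict)
    tf_profile: Dict[str, np.ndarray] = field(default_factory=dict)
    target_profile: Dict[str, np.ndarray] = field(default_factory=dict)
    expression_profile: Dict[str, np.ndarray] = field(default_factory=dict)
    pathway_profile: Dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_unique(self.mirna_ids, "miRNA")
        known = set(self.mirna_ids)
        for attr in ("precursor_seq", "mature_seq", "seed_seq"):
            block = getattr(self, attr)
            for mid, seq in block.items():
                if mid not in known:
                    raise ValueError(f"{attr} declares unknown miRNA {mid!r}")
                block[mid] = normalize_sequence(seq, mid)
        for attr in ("tf_profile", "target_profile"):
            self._check_vectors(attr, binary=True)
        for attr in ("expression_profile", "pathway_profile"):
            self._check_vectors(attr, binary=False)

    def _check_vectors(self, attr: str, binary: bool) -> None:
        block = getattr(self, attr)
        known = set(self.mirna_ids)
        length: Optional[int] = None
        for mid, vec in block.items():
            if mid not in known:
                raise ValueError(f"{attr} declares unknown miRNA {mid!r}")
            arr = np.asarray(vec, dtype=float)
            if arr.ndim != 1:
                raise ValueError(f"{attr}[{mid!r}] is not a vector")
            if length is None:
                length = arr.size
            elif arr.size != length:
                raise ValueError(
                    f"{attr}[{mid!r}] has length {arr.size}, expected {length}"
                )
            if binary:
                if not np.isin(arr, (0.0, 1.0)).all():
                    raise ValueError(f"{attr}[{mid!r}] contains non-binary values")
            else:
                if not np.isfinite(arr).all():
                    raise ValueError(f"{attr}[{mid!r}] contains non-finite values")
                if (arr < 0).any():
                    raise ValueError(f"{attr}[{mid!r}] contains negative values")
            block[mid] = arr

    def ids_with(self, *attrs: str) -> List[str]:
        """miRNA ids covered by every named feature block, in canonical order."""
        present = set(self.mirna_ids)
        for attr in attrs:
            present &= set(getattr(self, attr))
        return [m for m in self.mirna_ids if m in present]


@dataclass
class AssociationMatrix:
    """Binary nm x nd causal miRNA-disease association matrix MD."""

    values: np.ndarray
    mirna_ids: List[str]
    disease_ids: List[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        _check_unique(self.mirna_ids, "miRNA")
        _check_unique(self.disease_ids, "disease")
        if self.values.shape != (len(self.mirna_ids), len(self.disease_ids)):
            raise ValueError(
                f"association matrix shape {self.values.shape} does not match "
                f"{len(self.mirna_ids)} miRNAs x {len(self.disease_ids)} diseases"
            )
        if not np.isin(self.values, (0.0, 1.0)).all():
            raise ValueError("association matrix entries must be 0 or 1")

    @property
    def n_mirnas(self) -> int:
        return len(self.mirna_ids)

    @property
    def n_diseases(self) -> int:
        return len(self.disease_ids)

    def positive_pairs(self) -> List[Tuple[str, str]]:
        rows, cols = np.nonzero(self.values)
        return [(self.mirna_ids[i], self.disease_ids[j]) for i, j in zip(rows, cols)]

    def copy(self) -> "AssociationMatrix":
        return AssociationMatrix(
            self.values.copy(), list(self.mirna_ids), list(self.disease_ids)
        )


@dataclass
class SimilarityMatrix:
    """Symmetric similarity matrix over one id universe, tagged by metric."""

    values: np.ndarray
    ids: List[str]
    metric: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        _check_unique(self.ids, "entity")
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError(f"similarity matrix shape {self.values.shape} != ({n},{n})")
        if self.metric not in _VALID_METRICS:
            raise ValueError(f"unknown metric label {self.metric!r}")
        if not np.isfinite(self.values).all():
            raise ValueError("similarity matrix contains non-finite values")
        if np.abs(self.values - self.values.T).max(initial=0.0) > 1e-10:
            raise ValueError("similarity matrix is not symmetric")
        if self.values.size and (self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12):
            raise ValueError("similarity values outside [0, 1]")

    def index_of(self, entity: str) -> int:
        return self.ids.index(entity)


@dataclass
class DiseaseDAG:
    """Directed acyclic parent -> child graph of disease terms."""

    graph: nx.DiGraph

    def __post_init__(self) -> None:
        if not isinstance(self.graph, nx.DiGraph):
            g = nx.DiGraph()
            g.add_nodes_from(self.graph)  # pragma: no cover - convenience
            self.graph = g
        if not nx.is_directed_acyclic_graph(self.graph):
            raise ValueError("disease graph contains a cycle")

    @classmethod
    def from_edges(
        cls, edges: Sequence[Tuple[str, str]], nodes: Optional[Sequence[str]] = None
    ) -> "DiseaseDAG":
        g = nx.DiGraph()
        if nodes is not None:
            g.add_nodes_from(nodes)
            declared = set(nodes)
            for p, c in edges:
                if p not in declared or c not in declared:
                    raise ValueError(f"edge ({p!r}, {c!r}) references undeclared node")
        g.add_edges_from(edges)
        return cls(g)

    @property
    def nodes(self) -> List[str]:
        return list(self.graph.nodes)

    def __contains__(self, node: str) -> bool:
        return node in self.graph

    def ancestors_and_self(self, node: str) -> set:
        """T(D): the node plus its ancestor closure under parent->child edges."""
        if node not in self.graph:
            raise KeyError(f"unknown disease {node!r}")
        return nx.ancestors(self.graph, node) | {node}


@dataclass
class ScoreMatrix:
    """Real-valued nm x nd prediction matrix with provenance."""

    values: np.ndarray
    mirna_ids: List[str]
    disease_ids: List[str]
    provenance: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        _check_unique(self.mirna_ids, "miRNA")
        _check_unique(self.disease_ids, "disease")
        if self.values.shape != (len(self.mirna_ids), len(self.disease_ids)):
            raise ValueError(
                f"score matrix shape {self.values.shape} does not match id lists"
            )
        if not np.isfinite(self.values).all():
            raise ValueError("score matrix contains non-finite values")

    def score_of(self, mirna: str, disease: str) -> float:
        return float(
            self.values[self.mirna_ids.index(mirna), self.disease_ids.index(disease)]
        )
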