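"""File readers and writers.

Formats are deliberately plain: FASTA for sequences, TSV for feature tables,
association lists (``mirna_id<TAB>disease_id<TAB>label``), DAG edge lists
(``parent<TAB>child``) and score dumps.  Readers validate aggressively and
name the offending line or identifier in error messages; every writer/reader
pair round-trips exactly.
"""

from __future__ import annotations

import logging
import os
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .types import AssociationMatrix, DiseaseDAG, ScoreMatrix, SimilarityMatrix

log = logging.getLogger("mdcapnet")

__all__ = [
    "read_fasta",
    "read_feature_table",
    "write_feature_table",
    "read_associations",
    "write_associations",
    "read_dag_edges",
    "write_dag_edges",
    "write_score_matrix",
    "read_score_matrix",
    "write_similarity_matrix",
    "read_similarity_matrix",
]

SEQUENCE_LEVELS = ("precursor", "mature", "seed")


def read_fasta(path: str, level: str = "mature") -> Dict[str, str]:
    """Read a FASTA file into an ordered id -> sequence mapping.

    Sequences are uppercased and T is unified to U.  ``level`` is accepted
    for interface symmetry with the profile-set loaders; the parsing is
    level-independent.
    """
    if level not in SEQUENCE_LEVELS:
        raise ValueError(f"unknown sequence level {level!r}")
    from .types import normalize_sequence

    records: Dict[str, str] = {}
    name: Optional[str] = None
    chunks: List[str] = []

    def flush() -> None:
        if name is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise ValueError(f"empty sequence for FASTA record {name!r} in {path}")
        records[name] = normalize_sequence(seq, name)

    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                name = line[1:].split()[0] if line[1:].strip() else ""
                if not name:
                    raise ValueError(f"{path}:{lineno}: empty FASTA header")
                if name in records:
                    raise ValueError(f"{path}:{lineno}: duplicate FASTA header {name!r}")
                chunks = []
            else:
                if name is None:
                    raise ValueError(f"{path}:{lineno}: sequence before first header")
                chunks.append(line)
    flush()
    return records


def read_feature_table(path: str, kind: str) -> Dict[str, np.ndarray]:
    """Read a TSV feature table (header of feature names, first column id).

    ``kind='binary'`` validates entries in {0,1}; ``kind='continuous'``
    validates finite reals.
    """
    if kind not in ("binary", "continuous"):
        raise ValueError(f"unknown feature kind {kind!r}")
    out: Dict[str, np.ndarray] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise ValueError(f"{path}: empty file")
        ncols = len(header.split("\t"))
        for lineno, raw in enumerate(fh, 2):
            if not raw.strip():
                continue
            fields = raw.rstrip("\n").split("\t")
            if len(fields) != ncols:
                raise ValueError(
                    f"{path}:{lineno}: ragged row ({len(fields)} fields, "
                    f"expected {ncols})"
                )
            mid = fields[0]
            if mid in out:
                raise ValueError(f"{path}:{lineno}: duplicate id {mid!r}")
            try:
                vec = np.array([float(x) for x in fields[1:]])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric value ({exc})") from None
            if not np.isfinite(vec).all():
                raise ValueError(f"{path}:{lineno}: non-finite value for id {mid!r}")
            if kind == "binary" and not np.isin(vec, (0.0, 1.0)).all():
                raise ValueError(f"{path}:{lineno}: non-binary value for id {mid!r}")
            out[mid] = vec
    return out


def write_feature_table(table: Dict[str, np.ndarray], path: str,
                        feature_names: Optional[Sequence[str]] = None) -> None:
    ids = list(table)
    if not ids:
        raise ValueError("empty feature table")
    width = len(next(iter(table.values())))
    if feature_names is None:
        feature_names = [f"f{i}" for i in range(width)]
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(feature_names) + "\n")
        for mid in ids:
            vec = np.asarray(table[mid])
            fh.write(mid + "\t" + "\t".join(repr(float(v)) for v in vec) + "\n")


def read_associations(
    path: str,
    mirna_universe: Optional[Sequence[str]] = None,
    disease_universe: Optional[Sequence[str]] = None,
) -> Tuple[AssociationMatrix, List[Tuple[str, str]]]:
    """Read a causal association list into (MD, non-causal pair list).

    The TSV has a header and columns ``mirna_id, disease_id[, label]`` with
    label in {causal, non-causal}; a missing label means causal.  MD gets a 1
    exactly at causal pairs; non-causal pairs are returned separately for
    evaluation and are never set in MD.  Id lists default to the sorted union
    of observed ids unless explicit universes are supplied.
    """
    causal: List[Tuple[str, str]] = []
    noncausal: List[Tuple[str, str]] = []
    seen: set = set()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["mirna_id", "disease_id"]:
            raise ValueError(
                f"{path}: expected header starting 'mirna_id\\tdisease_id', got {header}"
            )
        for lineno, raw in enumerate(fh, 2):
            if not raw.strip():
                continue
            fields = raw.rstrip("\n").split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: need at least 2 columns")
            mid, did = fields[0], fields[1]
            label = fields[2] if len(fields) > 2 and fields[2] else "causal"
            if label not in ("causal", "non-causal"):
                raise ValueError(f"{path}:{lineno}: unknown label token {label!r}")
            key = (mid, did, label)
            if key in seen:
                log.warning("%s:%d: duplicate %s pair (%s, %s) ignored",
                            path, lineno, label, mid, did)
                continue
            seen.add(key)
            (causal if label == "causal" else noncausal).append((mid, did))

    if mirna_universe is None:
        mirna_universe = sorted({m for m, _ in causal} | {m for m, _ in noncausal})
    if disease_universe is None:
        disease_universe = sorted({d for _, d in causal} | {d for _, d in noncausal})
    m_idx = {m: i for i, m in enumerate(mirna_universe)}
    d_idx = {d: j for j, d in enumerate(disease_universe)}
    values = np.zeros((len(m_idx), len(d_idx)))
    for m, d in causal:
        if m not in m_idx or d not in d_idx:
            raise ValueError(f"pair ({m!r}, {d!r}) outside the supplied universe")
        values[m_idx[m], d_idx[d]] = 1.0
    md = AssociationMatrix(values, list(mirna_universe), list(disease_universe))
    return md, noncausal


def write_associations(md: AssociationMatrix, path: str,
                       noncausal: Sequence[Tuple[str, str]] = ()) -> None:
    with open(path, "w") as fh:
        fh.write("mirna_id\tdisease_id\tlabel\n")
        for m, d in md.positive_pairs():
            fh.write(f"{m}\t{d}\tcausal\n")
        for m, d in noncausal:
            fh.write(f"{m}\t{d}\tnon-causal\n")


def read_dag_edges(path: str) -> DiseaseDAG:
    """Read a ``parent<TAB>child`` edge list (header required) into a DAG."""
    edges: List[Tuple[str, str]] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["parent", "child"]:
            raise ValueError(f"{path}: expected header 'parent\\tchild', got {header}")
        for lineno, raw in enumerate(fh, 2):
            if not raw.strip():
                continue
            fields = raw.rstrip("\n").split("\t")
            if len(fields) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            edges.append((fields[0], fields[1]))
    return DiseaseDAG.from_edges(edges)


def write_dag_edges(dag: DiseaseDAG, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("parent\tchild\n")
        for p, c in dag.graph.edges:
            fh.write(f"{p}\t{c}\n")
        # isolated nodes are re-created on read only if they appear in an edge;
        # encode them as self-documenting no-parent markers is out of scope.


def write_score_matrix(scores: ScoreMatrix, path: str) -> None:
    """Write scores as long-format TSV sorted by descending score."""
    if not np.isfinite(scores.values).all():
        raise ValueError("score matrix contains non-finite values")
    nm, nd = scores.values.shape
    rows = []
    for i in range(nm):
        for j in range(nd):
            rows.append((scores.mirna_ids[i], scores.disease_ids[j],
                         float(scores.values[i, j])))
    rows.sort(key=lambda r: (-r[2], r[0], r[1]))
    with open(path, "w") as fh:
        fh.write("mirna_id\tdisease_id\tscore\n")
        for m, d, s in rows:
            fh.write(f"{m}\t{d}\t{s!r}\n")


def read_score_matrix(path: str) -> ScoreMatrix:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != ["mirna_id", "disease_id", "score"]:
        raise ValueError(f"{path}: unexpected columns {list(df.columns)}")
    mirnas = sorted(df["mirna_id"].astype(str).unique())
    diseases = sorted(df["disease_id"].astype(str).unique())
    values = np.zeros((len(mirnas), len(diseases)))
    m_idx = {m: i for i, m in enumerate(mirnas)}
    d_idx = {d: j for j, d in enumerate(diseases)}
    for m, d, s in df.itertuples(index=False):
        values[m_idx[str(m)], d_idx[str(d)]] = s
    return ScoreMatrix(values, mirnas, diseases, provenance=f"read:{os.path.basename(path)}")


def write_similarity_matrix(sim: SimilarityMatrix, path: str) -> None:
    """Square-matrix TSV with id header row and column."""
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(sim.ids) + "\n")
        for i, name in enumerate(sim.ids):
            fh.write(name + "\t" + "\t".join(repr(float(v)) for v in sim.values[i]) + "\n")


def read_similarity_matrix(path: str, metric: str) -> SimilarityMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    ids = [str(c) for c in df.columns]
    if [str(i) for i in df.index] != ids:
        raise ValueError(f"{path}: row and column ids disagree")
    return SimilarityMatrix(df.to_numpy(dtype=float), ids, metric)
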