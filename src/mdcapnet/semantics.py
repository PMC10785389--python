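"""Wang-style disease semantic similarity over a disease term DAG.

Each disease D defines a sub-DAG T(D): D itself plus its ancestor closure.
The semantic contribution of a term d in T(D) decays with distance from D:

    D_D(D) = 1
    D_D(d) = max { delta * D_D(d') : d' a child of d inside T(D) }

with semantic contribution factor delta (usually 0.5).  The semantic value
DC(D) sums all contributions, and the similarity of two diseases is the sum
of their joint contributions on the shared part of their sub-DAGs, scaled by
DC(Di) + DC(Dj).  Diseases with largely shared DAG structure score high;
disjoint ancestries score 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import networkx as nx
import numpy as np

from .types import DiseaseDAG, SimilarityMatrix

log = logging.getLogger("mdcapnet")

__all__ = ["SemanticDecomposition", "semantic_decomposition", "disease_similarity"]


@dataclass
class SemanticDecomposition:
    disease: str
    contributions: Dict[str, float]  # ancestor-or-self -> D_D(d)
    semantic_value: float  # DC(D)


def semantic_decomposition(
    dag: DiseaseDAG, disease: str, delta: float = 0.5
) -> SemanticDecomposition:
    """Contribution map D_D(.) and semantic value DC(D) for one disease."""
    if not 0 < delta < 1:
        raise ValueError("delta must be in (0, 1)")
    if disease not in dag:
        raise ValueError(f"unknown disease {disease!r}")
    closure = dag.ancestors_and_self(disease)
    sub = dag.graph.subgraph(closure)
    contributions: Dict[str, float] = {disease: 1.0}
    # reverse topological order: children before parents
    for node in reversed(list(nx.topological_sort(sub))):
        if node == disease:
            continue
        child_vals = [contributions[c] for c in sub.successors(node)]
        contributions[node] = delta * max(child_vals)
    return SemanticDecomposition(
        disease=disease,
        contributions=contributions,
        semantic_value=float(sum(contributions.values())),
    )


def disease_similarity(
    dag: DiseaseDAG,
    delta: float = 0.5,
    ids: Optional[Sequence[str]] = None,
) -> SimilarityMatrix:
    """Pairwise semantic similarity matrix DS over the DAG's diseases.

    ``ids`` optionally fixes the id universe; ids absent from the DAG get an
    off-diagonal row/column of 0 (diagonal 1) with a warning rather than
    being dropped.
    """
    if ids is None:
        ids = list(dag.nodes)
    if not ids:
        raise ValueError("empty disease universe")
    decomp: Dict[str, SemanticDecomposition] = {}
    for d in ids:
        if d in dag:
            decomp[d] = semantic_decomposition(dag, d, delta)
        else:
            log.warning("disease %r absent from the DAG; semantic row set to 0", d)
    n = len(ids)
    values = np.eye(n)
    for i in range(n):
        di = decomp.get(ids[i])
        if di is None:
            continue
        for j in range(i + 1, n):
            dj = decomp.get(ids[j])
            if dj is None:
                continue
            shared = di.contributions.keys() & dj.contributions.keys()
            if shared:
                num = sum(di.contributions[d] + dj.contributions[d] for d in shared)
                values[i, j] = values[j, i] = num / (
                    di.semantic_value + dj.semantic_value
                )
    return SimilarityMatrix(np.clip(values, 0.0, 1.0), list(ids), "disease_semantic")
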