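"""Deep network imputation: binarize, embed, re-link.

The known similarity and association networks are sparse and incomplete, so
before label propagation each similarity matrix is truncated at a
per-metric threshold xi into a binary graph, the graph is embedded with
biased random walks + skip-gram (see :mod:`mdcapnet.embedding`), and a
logistic link classifier on Hadamard pair features scores every unobserved
pair of the legal type.  Candidates whose predicted link probability
reaches the acceptance cutoff pi (default 0.95) are added; observed edges
are never removed.  The bipartite causal association network is re-linked
the same way over the joint miRNA+disease node set, with an optional
holdout mask that pins evaluation pairs out of reach of the imputer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.linear_model import LogisticRegression

from .config import WalkParams
from .embedding import embed_adjacency
from .types import AssociationMatrix, SimilarityMatrix

log = logging.getLogger("mdcapnet")

__all__ = [
    "BinaryNetwork",
    "EmbeddingTable",
    "ImputedNetwork",
    "binarize",
    "embed_graph",
    "impute_links",
    "score_candidate_links",
    "impute_association_network",
]

MIN_EDGES_FOR_IMPUTATION = 10


@dataclass
class BinaryNetwork:
    """{0,1} network: square symmetric (similarity) or rectangular (association)."""

    adjacency: np.ndarray
    row_ids: List[str]
    col_ids: Optional[List[str]] = None  # None => square similarity network
    origin: str = "similarity"
    threshold_used: Optional[float] = None

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency, dtype=float)
        if not np.isin(self.adjacency, (0.0, 1.0)).all():
            raise ValueError("binary network entries must be 0 or 1")
        if self.col_ids is None:
            n = len(self.row_ids)
            if self.adjacency.shape != (n, n):
                raise ValueError("square network shape mismatch")
            if (self.adjacency != self.adjacency.T).any():
                raise ValueError("square network must be symmetric")
            if np.diagonal(self.adjacency).any():
                raise ValueError("square network must have a zero diagonal")
        else:
            if self.adjacency.shape != (len(self.row_ids), len(self.col_ids)):
                raise ValueError("bipartite network shape mismatch")
        if self.origin not in ("similarity", "association"):
            raise ValueError(f"unknown origin {self.origin!r}")

    @property
    def is_bipartite(self) -> bool:
        return self.col_ids is not None

    def n_edges(self) -> int:
        if self.is_bipartite:
            return int(self.adjacency.sum())
        return int(self.adjacency.sum()) // 2


@dataclass
class EmbeddingTable:
    """Per-node embedding vectors plus the walk parameters that produced them."""

    node_ids: List[str]
    vectors: np.ndarray
    params: WalkParams
    seed: int

    def __post_init__(self) -> None:
        if self.vectors.shape[0] != len(self.node_ids):
            raise ValueError("embedding table shape mismatch")
        if not np.isfinite(self.vectors).all():
            raise ValueError("non-finite embedding vectors")

    def vector(self, node: str) -> np.ndarray:
        return self.vectors[self.node_ids.index(node)]


@dataclass
class ImputedNetwork:
    """Observed ∪ imputed edges plus the link scores of the additions."""

    network: BinaryNetwork
    imputed_edges: List[Tuple[str, str, float]] = field(default_factory=list)
    summary: Dict[str, float] = field(default_factory=dict)


def binarize(ms: SimilarityMatrix, xi: float) -> BinaryNetwork:
    """Truncate a similarity matrix at threshold xi into a binary graph.

    An edge (i, j), i != j, exists iff similarity >= xi; the diagonal is
    dropped.
    """
    if not 0 < xi < 1:
        raise ValueError("threshold xi must be in (0, 1)")
    adj = (ms.values >= xi).astype(float)
    np.fill_diagonal(adj, 0.0)
    adj = np.maximum(adj, adj.T)  # symmetry is inherited; be explicit
    return BinaryNetwork(adj, list(ms.ids), None, "similarity", xi)


def _bipartite_node_ids(net: BinaryNetwork) -> List[str]:
    return [f"m:{m}" for m in net.row_ids] + [f"d:{d}" for d in net.col_ids]


def _full_adjacency(net: BinaryNetwork) -> np.ndarray:
    if not net.is_bipartite:
        return net.adjacency
    nm, nd = net.adjacency.shape
    full = np.zeros((nm + nd, nm + nd))
    full[:nm, nm:] = net.adjacency
    full[nm:, :nm] = net.adjacency.T
    return full


def embed_graph(net: BinaryNetwork, params: Optional[WalkParams] = None,
                seed: int = 0) -> EmbeddingTable:
    """Embed a binary network's nodes; bipartite networks embed both sides."""
    if params is None:
        params = WalkParams()
    full = _full_adjacency(net)
    if not full.any():
        raise ValueError("cannot embed an edgeless network")
    vectors = embed_adjacency(full, params, seed)
    node_ids = _bipartite_node_ids(net) if net.is_bipartite else list(net.row_ids)
    return EmbeddingTable(node_ids, vectors, params, seed)


def _fit_link_classifier(
    emb_vectors: np.ndarray,
    pos_pairs: np.ndarray,
    neg_pairs: np.ndarray,
) -> LogisticRegression:
    X_pos = emb_vectors[pos_pairs[:, 0]] * emb_vectors[pos_pairs[:, 1]]
    X_neg = emb_vectors[neg_pairs[:, 0]] * emb_vectors[neg_pairs[:, 1]]
    X = np.vstack([X_pos, X_neg])
    y = np.concatenate([np.ones(len(X_pos)), np.zeros(len(X_neg))])
    clf = LogisticRegression(max_iter=1000)
    clf.fit(X, y)
    return clf


def _sample_rows(rows: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    if len(rows) <= k:
        return rows
    idx = rng.choice(len(rows), size=k, replace=False)
    return rows[idx]


def score_candidate_links(
    net: BinaryNetwork,
    emb: EmbeddingTable,
    pairs: np.ndarray,
    seed: int = 0,
) -> np.ndarray:
    """Link probability for given candidate index pairs of a square network.

    Trains the same edge-vs-sampled-nonedge logistic model used by
    :func:`impute_links` and returns predicted probabilities for ``pairs``
    (an array of (i, j) node index rows).
    """
    if net.is_bipartite:
        raise ValueError("score_candidate_links expects a square network")
    n = len(net.row_ids)
    iu = np.triu_indices(n, k=1)
    observed = net.adjacency[iu] > 0
    pos = np.column_stack([iu[0][observed], iu[1][observed]])
    nonedges = np.column_stack([iu[0][~observed], iu[1][~observed]])
    if len(pos) == 0 or len(nonedges) == 0:
        raise ValueError("need both edges and non-edges to fit a link model")
    rng = np.random.default_rng(seed)
    neg = _sample_rows(nonedges, len(pos), rng)
    clf = _fit_link_classifier(emb.vectors, pos, neg)
    pairs = np.asarray(pairs)
    return clf.predict_proba(emb.vectors[pairs[:, 0]] * emb.vectors[pairs[:, 1]])[:, 1]


def impute_links(
    net: BinaryNetwork,
    emb: EmbeddingTable,
    link_probability: float = 0.95,
    seed: int = 0,
) -> ImputedNetwork:
    """Score unobserved same-type pairs and add confident links.

    Positives are the observed edges; an equal number of non-edges is
    sampled as negatives; pair features are Hadamard products of the two
    node embeddings.  Candidates with predicted probability >=
    ``link_probability`` enter the re-linked network.  Networks with fewer
    than 10 edges are returned unchanged with a warning.
    """
    if net.is_bipartite:
        raise ValueError("use impute_association_network for bipartite networks")
    if emb.node_ids != list(net.row_ids):
        raise ValueError("embedding does not cover the network's nodes")
    n = len(net.row_ids)
    iu = np.triu_indices(n, k=1)
    observed = net.adjacency[iu] > 0
    pos = np.column_stack([iu[0][observed], iu[1][observed]])
    if len(pos) < MIN_EDGES_FOR_IMPUTATION:
        log.warning("only %d edges; skipping imputation for %s network",
                    len(pos), net.origin)
        return ImputedNetwork(net, [], {"skipped": 1.0, "n_edges": float(len(pos))})
    candidates = np.column_stack([iu[0][~observed], iu[1][~observed]])
    if len(candidates) == 0:
        return ImputedNetwork(net, [], {"skipped": 1.0, "n_edges": float(len(pos))})
    probs = score_candidate_links(net, emb, candidates, seed)
    keep = probs >= link_probability
    adj = net.adjacency.copy()
    imputed: List[Tuple[str, str, float]] = []
    for (i, j), p in zip(candidates[keep], probs[keep]):
        adj[i, j] = adj[j, i] = 1.0
        imputed.append((net.row_ids[i], net.row_ids[j], float(p)))
    log.info("%s network: %d observed edges, %d imputed", net.origin, len(pos),
             len(imputed))
    out = BinaryNetwork(adj, list(net.row_ids), None, net.origin, net.threshold_used)
    return ImputedNetwork(out, imputed, {
        "n_edges": float(len(pos)),
        "n_imputed": float(len(imputed)),
        "n_candidates": float(len(candidates)),
    })


def impute_association_network(
    md: AssociationMatrix,
    params: Optional[WalkParams] = None,
    link_probability: float = 0.95,
    seed: int = 0,
    holdout_mask: Optional[Sequence[Tuple[str, str]]] = None,
) -> ImputedNetwork:
    """Re-link the bipartite causal association network.

    ``md`` must contain training positives only; ``holdout_mask`` lists
    evaluation pairs which must not be observed (leakage check) and are
    never imputed.
    """
    nm, nd = md.values.shape
    if md.values.sum() == 0:
        raise ValueError("empty training association matrix")
    mask_idx: set = set()
    if holdout_mask:
        m_pos = {m: i for i, m in enumerate(md.mirna_ids)}
        d_pos = {d: j for j, d in enumerate(md.disease_ids)}
        for m, d in holdout_mask:
            if m in m_pos and d in d_pos:
                i, j = m_pos[m], d_pos[d]
                if md.values[i, j]:
                    raise ValueError(
                        f"holdout pair ({m!r}, {d!r}) is present in the training "
                        "matrix: data leakage"
                    )
                mask_idx.add((i, j))
    net = BinaryNetwork(md.values.copy(), list(md.mirna_ids), list(md.disease_ids),
                        "association", None)
    n_pos = net.n_edges()
    if n_pos < MIN_EDGES_FOR_IMPUTATION:
        log.warning("only %d association edges; skipping imputation", n_pos)
        return ImputedNetwork(net, [], {"skipped": 1.0, "n_edges": float(n_pos)})
    emb = embed_graph(net, params, seed)
    rows, cols = np.nonzero(md.values)
    pos = np.column_stack([rows, nm + cols])  # joint node indices
    zr, zc = np.nonzero(md.values == 0)
    legal = np.array([(i, j) not in mask_idx for i, j in zip(zr, zc)])
    candidates = np.column_stack([zr[legal], nm + zc[legal]])
    if len(candidates) == 0:
        return ImputedNetwork(net, [], {"skipped": 1.0, "n_edges": float(n_pos)})
    rng = np.random.default_rng(seed)
    neg = _sample_rows(candidates, len(pos), rng)
    clf = _fit_link_classifier(emb.vectors, pos, neg)
    probs = clf.predict_proba(
        emb.vectors[candidates[:, 0]] * emb.vectors[candidates[:, 1]])[:, 1]
    keep = probs >= link_probability
    adj = md.values.copy()
    imputed: List[Tuple[str, str, float]] = []
    for (i, jj), p in zip(candidates[keep], probs[keep]):
        j = jj - nm
        adj[i, j] = 1.0
        imputed.append((md.mirna_ids[i], md.disease_ids[j], float(p)))
    log.info("association network: %d observed, %d imputed", n_pos, len(imputed))
    out = BinaryNetwork(adj, list(md.mirna_ids), list(md.disease_ids),
                        "association", None)
    return ImputedNetwork(out, imputed, {
        "n_edges": float(n_pos),
        "n_imputed": float(len(imputed)),
        "n_candidates": float(len(candidates)),
    })
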