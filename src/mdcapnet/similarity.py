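"""miRNA similarity metrics.

Six pairwise miRNA similarity matrices feed the predictor:

* ``seq`` — Levenshtein-based similarity of precursor/mature/seed sequences,
  combined as a weighted sum (defaults 0.80/0.15/0.05);
* ``tf`` / ``gene`` — Levenshtein similarity of the binary TF-regulator and
  target-gene profiles serialized as 0/1 strings;
* ``expr`` / ``pathway`` — Tanimoto coefficient of the continuous expression
  and pathway-enrichment profiles;
* ``gip`` — Gaussian interaction profile kernel on rows of the training
  association matrix.

The Levenshtein similarity of two strings is ``1 - LD/(len1 + len2)`` with
LD the standard unit-cost edit distance, so equal-length strings always
score in [0.5, 1] (LD is at most the common length, i.e. half the summed
lengths); for very unequal lengths the score can drop below 0.5.
"""

from __future__ import annotations

import logging
from typing import Dict, Iterable, List, Mapping, Tuple

import edlib
import numpy as np

from .types import AssociationMatrix, MirnaProfileSet, SimilarityMatrix

log = logging.getLogger("mdcapnet")

__all__ = [
    "levenshtein_distance",
    "levenshtein_similarity",
    "sequence_similarity",
    "binary_profile_similarity",
    "tanimoto_similarity",
    "continuous_similarity",
    "normalize_expression",
    "pathway_features",
    "gip_kernel",
]


def levenshtein_distance(s1: str, s2: str) -> int:
    """Standard unit-cost (insert/delete/substitute) edit distance."""
    if not s1 or not s2:
        raise ValueError("Levenshtein similarity is undefined for empty strings")
    return int(edlib.align(s1, s2, task="distance")["editDistance"])


def levenshtein_similarity(s1: str, s2: str) -> float:
    """1 - LD(s1,s2)/(len(s1)+len(s2)); symmetric, 1 iff the strings match."""
    return 1.0 - levenshtein_distance(s1, s2) / (len(s1) + len(s2))


def _pairwise_levenshtein(strings: List[str]) -> np.ndarray:
    n = len(strings)
    out = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = levenshtein_similarity(strings[i], strings[j])
    return out


def sequence_similarity(
    profiles: MirnaProfileSet,
    weights: Mapping[str, float] | None = None,
) -> SimilarityMatrix:
    """Weighted sum of precursor/mature/seed Levenshtein similarity matrices."""
    if weights is None:
        weights = {"precursor": 0.80, "mature": 0.15, "seed": 0.05}
    if abs(sum(weights.values()) - 1.0) > 1e-9:
        raise ValueError("sequence weights must sum to 1")
    ids = profiles.ids_with("precursor_seq", "mature_seq", "seed_seq")
    missing = [m for m in profiles.mirna_ids if m not in set(ids)]
    if missing:
        raise ValueError(f"miRNAs missing a sequence level: {missing}")
    total = np.zeros((len(ids), len(ids)))
    for level, attr in (("precursor", "precursor_seq"), ("mature", "mature_seq"),
                        ("seed", "seed_seq")):
        block = getattr(profiles, attr)
        total += weights[level] * _pairwise_levenshtein([block[m] for m in ids])
    return SimilarityMatrix(np.clip(total, 0.0, 1.0), ids, "seq")


def binary_profile_similarity(profiles: MirnaProfileSet, which: str) -> SimilarityMatrix:
    """Levenshtein similarity of binary profiles serialized as 0/1 strings.

    Feature order is the fixed order of the profile vectors, so serialized
    strings are reproducible across runs.  All profiles share one length L,
    hence the scores lie in [0.5, 1].
    """
    attr, metric = {"tf": ("tf_profile", "tf"), "target": ("target_profile", "gene")}[which]
    block: Dict[str, np.ndarray] = getattr(profiles, attr)
    ids = [m for m in profiles.mirna_ids if m in block]
    if not ids:
        raise ValueError(f"no miRNAs carry a {which} profile")
    strings = ["".join("1" if v else "0" for v in block[m]) for m in ids]
    lengths = {len(s) for s in strings}
    if len(lengths) != 1:
        raise ValueError(f"{which} profiles have mismatched lengths {sorted(lengths)}")
    return SimilarityMatrix(_pairwise_levenshtein(strings), ids, metric)


def tanimoto_similarity(v1: np.ndarray, v2: np.ndarray) -> float:
    """Tanimoto coefficient a.b / (|a|^2 + |b|^2 - a.b).

    On binary vectors this is the Jaccard index; on nonnegative reals it
    lies in [0, 1] and equals 1 iff the vectors coincide (and are nonzero).
    """
    a = np.asarray(v1, dtype=float)
    b = np.asarray(v2, dtype=float)
    if a.shape != b.shape:
        raise ValueError("tanimoto: vectors have different lengths")
    dot = float(a @ b)
    denom = float(a @ a) + float(b @ b) - dot
    if denom == 0.0:
        raise ValueError("tanimoto undefined: both vectors are all-zero")
    return dot / denom


def continuous_similarity(profiles: MirnaProfileSet, which: str) -> SimilarityMatrix:
    """Pairwise Tanimoto matrix over a continuous feature block."""
    attr, metric = {
        "expression": ("expression_profile", "expr"),
        "pathway": ("pathway_profile", "pathway"),
    }[which]
    block: Dict[str, np.ndarray] = getattr(profiles, attr)
    ids = [m for m in profiles.mirna_ids if m in block]
    if not ids:
        raise ValueError(f"no miRNAs carry a {which} profile")
    X = np.stack([block[m] for m in ids])
    sq = np.einsum("ij,ij->i", X, X)
    zero = np.flatnonzero(sq == 0)
    if zero.size:
        raise ValueError(f"all-zero {which} profile for miRNA {ids[zero[0]]!r}")
    G = X @ X.T
    denom = sq[:, None] + sq[None, :] - G
    values = G / denom
    values = np.clip((values + values.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(values, ids, metric)


def normalize_expression(raw: Mapping[str, np.ndarray]) -> Dict[str, np.ndarray]:
    """Remove per-cell-type scale: divide each column by its total, then log1p.

    Columns (cell types) that are zero across all miRNAs carry no signal and
    are dropped with a warning.
    """
    ids = list(raw)
    X = np.stack([np.asarray(raw[m], dtype=float) for m in ids])
    if (X < 0).any():
        raise ValueError("expression values must be nonnegative")
    totals = X.sum(axis=0)
    keep = totals > 0
    if not keep.all():
        log.warning("dropping %d all-zero expression columns", int((~keep).sum()))
    X = np.log1p(X[:, keep] / totals[keep])
    return {m: X[i] for i, m in enumerate(ids)}


def pathway_features(
    pvals: Mapping[Tuple[str, str], float],
    cap: float = 20.0,
    min_significant: int = 3,
    alpha: float = 0.05,
) -> Dict[str, np.ndarray]:
    """Turn per-(miRNA, pathway) enrichment p-values into feature vectors.

    Keeps only pathways where at least ``min_significant`` miRNAs reach
    p < ``alpha``; feature value is -log10(p) capped at ``cap``; pairs with
    no recorded p-value contribute 0.
    """
    mirnas: List[str] = []
    pathways: List[str] = []
    for (mid, pw), p in pvals.items():
        if p <= 0 or p > 1:
            raise ValueError(f"p-value out of (0, 1] for ({mid!r}, {pw!r}): {p}")
        if mid not in mirnas:
            mirnas.append(mid)
        if pw not in pathways:
            pathways.append(pw)
    kept = [pw for pw in pathways
            if sum(1 for (m, q), p in pvals.items() if q == pw and p < alpha)
            >= min_significant]
    kept.sort()
    out: Dict[str, np.ndarray] = {}
    for mid in mirnas:
        vec = np.zeros(len(kept))
        for j, pw in enumerate(kept):
            p = pvals.get((mid, pw))
            if p is not None:
                vec[j] = min(-np.log10(p), cap)
        out[mid] = vec
    return out


def gip_kernel(assoc: AssociationMatrix, axis: str = "mirna") -> SimilarityMatrix:
    """Gaussian interaction profile kernel on association-matrix profiles.

    GM(i,j) = exp(-gamma * ||IP(i) - IP(j)||^2) where IP(i) is entity i's
    row (miRNA axis) or column (disease axis) of MD and the bandwidth is
    gamma = 1 / mean_i ||IP(i)||^2 (the van Laarhoven convention with
    gamma' = 1).
    """
    if axis == "mirna":
        profiles, ids = assoc.values, assoc.mirna_ids
    elif axis == "disease":
        profiles, ids = assoc.values.T, assoc.disease_ids
    else:
        raise ValueError(f"unknown axis {axis!r}")
    norms = np.einsum("ij,ij->i", profiles, profiles)
    mean_norm = norms.mean()
    if mean_norm == 0:
        raise ValueError("GIP bandwidth undefined: association matrix is all-zero")
    gamma = 1.0 / mean_norm
    sq_dists = norms[:, None] + norms[None, :] - 2.0 * (profiles @ profiles.T)
    values = np.exp(-gamma * np.maximum(sq_dists, 0.0))
    values = (values + values.T) / 2.0
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(values, list(ids), "gip")
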