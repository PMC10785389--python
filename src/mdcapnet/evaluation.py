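"""Evaluation protocol: folds, AUROC, rank-sum tests, score fusion.

The published protocol is reproduced at desk scale: known causal pairs are
split into folds (or one independent test split) *before* network
imputation; the model scores every miRNA-disease pair; AUROC is computed
for causal-versus-non-disease discrimination (negatives drawn from pairs
with no recorded association of any kind) and, reusing the same scores
without refitting, for the harder causal-versus-non-causal discrimination,
together with a Wilcoxon rank-sum test of the score difference.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats
from sklearn.metrics import roc_curve

from .types import AssociationMatrix, ScoreMatrix, SIMILARITY_METRICS

log = logging.getLogger("mdcapnet")

__all__ = [
    "EvaluationSplit",
    "EvaluationReport",
    "make_folds",
    "independent_split",
    "auroc",
    "wilcoxon_rank_sum",
    "evaluate_causal_vs_nondisease",
    "evaluate_causal_vs_noncausal",
    "combine_metrics",
    "grid_search_weights",
    "association_hash",
    "assert_no_leakage",
]

Pair = Tuple[str, str]


@dataclass
class EvaluationSplit:
    train_positives: List[Pair]
    test_positives: List[Pair]
    fold_id: int
    seed: int

    def __post_init__(self) -> None:
        overlap = set(self.train_positives) & set(self.test_positives)
        if overlap:
            raise ValueError(f"train/test overlap: {sorted(overlap)[:3]}")


@dataclass
class EvaluationReport:
    auroc: float
    roc_fpr: np.ndarray
    roc_tpr: np.ndarray
    roc_thresholds: np.ndarray
    n_positives: int
    n_negatives: int
    ranksum_statistic: Optional[float] = None
    ranksum_pvalue: Optional[float] = None
    group_summaries: Dict[str, Dict[str, float]] = field(default_factory=dict)


def make_folds(md: AssociationMatrix, k: int, seed: int) -> List[EvaluationSplit]:
    """Partition the known causal pairs into k test folds (sizes within 1)."""
    positives = md.positive_pairs()
    if k < 2:
        raise ValueError("need at least 2 folds")
    if k > len(positives):
        raise ValueError(f"cannot make {k} folds from {len(positives)} positives")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(positives))
    folds: List[EvaluationSplit] = []
    bounds = np.linspace(0, len(positives), k + 1).round().astype(int)
    for f in range(k):
        test_idx = set(order[bounds[f]:bounds[f + 1]].tolist())
        test = [positives[i] for i in sorted(test_idx)]
        train = [p for i, p in enumerate(positives) if i not in test_idx]
        folds.append(EvaluationSplit(train, test, fold_id=f, seed=seed))
    return folds


def independent_split(
    md: AssociationMatrix, test_fraction: float, seed: int
) -> EvaluationSplit:
    """Single train/test split of the known causal pairs (default 1/5 test)."""
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    positives = md.positive_pairs()
    n_test = max(1, int(round(test_fraction * len(positives))))
    if n_test >= len(positives):
        raise ValueError("test fraction leaves no training positives")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(positives))
    test_idx = set(order[:n_test].tolist())
    test = [positives[i] for i in sorted(test_idx)]
    train = [p for i, p in enumerate(positives) if i not in test_idx]
    return EvaluationSplit(train, test, fold_id=-1, seed=seed)


def auroc(scored: Sequence[Tuple[float, int]]) -> float:
    """Rank-based AUROC; ties contribute 1/2 (Mann-Whitney normalization)."""
    scores = np.array([s for s, _ in scored], dtype=float)
    labels = np.array([l for _, l in scored], dtype=int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC needs both classes present")
    ranks = stats.rankdata(scores)
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def wilcoxon_rank_sum(
    group_a: Sequence[float], group_b: Sequence[float]
) -> Tuple[float, float]:
    """Two-sided rank-sum test (exact for both n <= 8 without ties, else
    tie-corrected normal approximation).  Returns (U statistic of A, p)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("rank-sum test needs both groups nonempty")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        log.warning("rank-sum: all values identical; p = 1")
        return float(a.size * b.size / 2.0), 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (a.size <= 8 and b.size <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def _pair_scores(scores: ScoreMatrix, pairs: Iterable[Pair]) -> np.ndarray:
    m_idx = {m: i for i, m in enumerate(scores.mirna_ids)}
    d_idx = {d: j for j, d in enumerate(scores.disease_ids)}
    out = []
    for m, d in pairs:
        if m not in m_idx or d not in d_idx:
            raise ValueError(f"pair ({m!r}, {d!r}) outside the score matrix")
        out.append(scores.values[m_idx[m], d_idx[d]])
    return np.array(out, dtype=float)


def _summary(values: np.ndarray) -> Dict[str, float]:
    return {
        "n": float(values.size),
        "mean": float(values.mean()),
        "median": float(np.median(values)),
    }


def sample_nondisease_pairs(
    scores: ScoreMatrix,
    exclude: Iterable[Pair],
    n: Optional[int],
    seed: int,
) -> List[Pair]:
    """Seeded sample of pairs with no recorded association of any kind."""
    excluded = set(exclude)
    universe = [
        (m, d)
        for m in scores.mirna_ids
        for d in scores.disease_ids
        if (m, d) not in excluded
    ]
    if not universe:
        raise ValueError("no non-disease pairs available")
    if n is None or n >= len(universe):
        if n is not None and n > len(universe):
            raise ValueError(
                f"requested {n} non-disease negatives, only {len(universe)} exist"
            )
        return universe
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(universe), size=n, replace=False)
    return [universe[i] for i in idx]


def evaluate_causal_vs_nondisease(
    scores: ScoreMatrix,
    split: EvaluationSplit,
    known_pairs: Iterable[Pair],
    negative_ratio: Optional[int] = None,
    seed: Optional[int] = None,
) -> EvaluationReport:
    """Test-fold causal positives vs (sampled) unrelated pairs.

    ``known_pairs`` must list every pair with *any* recorded association
    (causal, train or test, plus non-causal) so negatives are genuinely
    unrelated.  ``negative_ratio`` = None uses all unrelated pairs.
    """
    positives = split.test_positives
    if not positives:
        raise ValueError("empty test fold")
    n_neg = None if negative_ratio is None else negative_ratio * len(positives)
    negatives = sample_nondisease_pairs(
        scores, known_pairs, n_neg, split.seed if seed is None else seed
    )
    pos_scores = _pair_scores(scores, positives)
    neg_scores = _pair_scores(scores, negatives)
    scored = [(s, 1) for s in pos_scores] + [(s, 0) for s in neg_scores]
    y = np.array([l for _, l in scored])
    s = np.array([v for v, _ in scored])
    fpr, tpr, thr = roc_curve(y, s)
    return EvaluationReport(
        auroc=auroc(scored),
        roc_fpr=fpr, roc_tpr=tpr, roc_thresholds=thr,
        n_positives=len(positives), n_negatives=len(negatives),
        group_summaries={"causal": _summary(pos_scores),
                         "non-disease": _summary(neg_scores)},
    )


def evaluate_causal_vs_noncausal(
    scores: ScoreMatrix,
    causal_pairs: Sequence[Pair],
    noncausal_pairs: Sequence[Pair],
) -> EvaluationReport:
    """Causal vs non-causal discrimination on the *same* score matrix.

    By contract the scores are the ones already produced for the
    causal-vs-non-disease task: no refit happens here.
    """
    if not causal_pairs or not noncausal_pairs:
        raise ValueError("both causal and non-causal groups must be nonempty")
    pos = _pair_scores(scores, causal_pairs)
    neg = _pair_scores(scores, noncausal_pairs)
    scored = [(s, 1) for s in pos] + [(s, 0) for s in neg]
    stat, pval = wilcoxon_rank_sum(pos, neg)
    y = np.array([l for _, l in scored])
    s = np.array([v for v, _ in scored])
    fpr, tpr, thr = roc_curve(y, s)
    return EvaluationReport(
        auroc=auroc(scored),
        roc_fpr=fpr, roc_tpr=tpr, roc_thresholds=thr,
        n_positives=len(pos), n_negatives=len(neg),
        ranksum_statistic=stat, ranksum_pvalue=pval,
        group_summaries={"causal": _summary(pos), "non-causal": _summary(neg)},
    )


def combine_metrics(
    scores: Mapping[str, ScoreMatrix],
    weights: Mapping[str, float],
    coverage: Optional[Mapping[str, Sequence[str]]] = None,
    renormalize: bool = False,
) -> ScoreMatrix:
    """Entrywise weighted sum of per-metric score matrices.

    ``coverage`` optionally maps a metric to the miRNAs it genuinely covers;
    rows outside a metric's coverage contribute 0 for that metric and the
    remaining weights are renormalized per row.  A metric named in
    ``weights`` but absent from ``scores`` raises unless ``renormalize``.
    """
    missing = [m for m in weights if m not in scores]
    if missing and not renormalize:
        raise ValueError(f"missing metric scores {missing}; pass renormalize=True "
                         "to drop them")
    use = {m: w for m, w in weights.items() if m in scores}
    total = sum(use.values())
    if total <= 0:
        raise ValueError("no usable fusion weight mass")
    use = {m: w / total for m, w in use.items()}

    first = next(iter(scores.values()))
    mirnas, diseases = first.mirna_ids, first.disease_ids
    for m, sm in scores.items():
        if sm.mirna_ids != mirnas or sm.disease_ids != diseases:
            raise ValueError(f"metric {m!r} has a different id universe")
    num = np.zeros_like(first.values)
    denom = np.zeros(len(mirnas))
    for metric, w in use.items():
        mask = np.ones(len(mirnas))
        if coverage is not None and metric in coverage:
            covered = set(coverage[metric])
            mask = np.array([1.0 if m in covered else 0.0 for m in mirnas])
        num += w * mask[:, None] * scores[metric].values
        denom += w * mask
    safe = np.where(denom > 0, denom, 1.0)
    combined = num / safe[:, None]
    prov = "combined:" + ",".join(f"{m}={use[m]:.4g}" for m in use)
    return ScoreMatrix(combined, list(mirnas), list(diseases), provenance=prov)


def _simplex_grid(n: int, steps: int):
    """All nonnegative integer compositions of `steps` into n parts."""
    if n == 1:
        yield (steps,)
        return
    for first in range(steps + 1):
        for rest in _simplex_grid(n - 1, steps - first):
            yield (first, *rest)


def grid_search_weights(
    scores: Mapping[str, ScoreMatrix],
    positives: Sequence[Pair],
    negatives: Sequence[Pair],
    step: float = 0.05,
) -> Dict[str, float]:
    """Exhaustive simplex search for fusion weights maximizing validation AUROC.

    Ties break toward the lexicographically smallest weight vector in metric
    order.  The grid has C(1/step + n - 1, n - 1) points; for six metrics at
    step 0.05 that is ~53k evaluations, so prefer a coarser step there.
    """
    metrics = [m for m in SIMILARITY_METRICS if m in scores] or sorted(scores)
    if len(metrics) < 2:
        raise ValueError("grid search needs at least two metrics")
    steps = round(1.0 / step)
    if abs(steps * step - 1.0) > 1e-9:
        raise ValueError("step must divide 1")
    pos_mats = np.stack([_pair_scores(scores[m], positives) for m in metrics])
    neg_mats = np.stack([_pair_scores(scores[m], negatives) for m in metrics])
    labels = np.concatenate([np.ones(pos_mats.shape[1]), np.zeros(neg_mats.shape[1])])
    best: Optional[Tuple[float, Tuple[int, ...]]] = None
    for comp in _simplex_grid(len(metrics), steps):
        w = np.array(comp, dtype=float) / steps
        s = np.concatenate([w @ pos_mats, w @ neg_mats])
        a = auroc(list(zip(s, labels.astype(int))))
        key = (a, tuple(-c for c in comp))  # maximize auroc, then lexicographic min
        if best is None or key > best:
            best = key
            best_comp = comp
    return {m: c / steps for m, c in zip(metrics, best_comp)}


def association_hash(values: np.ndarray) -> str:
    """Stable content hash of a binary association matrix (leakage audit)."""
    arr = np.ascontiguousarray(values, dtype=np.uint8)
    h = hashlib.sha256()
    h.update(str(arr.shape).encode())
    h.update(arr.tobytes())
    return h.hexdigest()


def assert_no_leakage(
    train_md: AssociationMatrix, test_pairs: Iterable[Pair]
) -> str:
    """Verify no test pair is present in a training structure; return its hash."""
    m_idx = {m: i for i, m in enumerate(train_md.mirna_ids)}
    d_idx = {d: j for j, d in enumerate(train_md.disease_ids)}
    for m, d in test_pairs:
        if m in m_idx and d in d_idx and train_md.values[m_idx[m], d_idx[d]]:
            raise AssertionError(
                f"leakage: test pair ({m!r}, {d!r}) present in training matrix"
            )
    return association_hash(train_md.values)
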