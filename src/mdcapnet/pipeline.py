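"""End-to-end orchestration: similarities -> imputation -> propagation -> fusion.

One pipeline run takes a data bundle (miRNA profiles, disease DAG, causal
association matrix, non-causal pair list) and an evaluation split, and:

1. computes the six miRNA similarity matrices and the disease semantic
   similarity matrix from *training* data only (the split's test positives
   are removed from MD before anything else — in particular before network
   imputation);
2. binarizes each similarity matrix at its per-metric threshold and
   re-links both the similarity networks and the bipartite association
   network via graph embeddings (skippable with ``imputation_enabled=False``
   for the ablation);
3. solves the two graph-regularized label-propagation problems per metric
   and fuses miRNA-space and disease-space solutions;
4. combines the six per-metric score matrices with the published fusion
   weights, renormalizing over the metrics that cover each miRNA;
5. evaluates causal-vs-non-disease and causal-vs-non-causal discrimination
   on the held-out pairs, reusing the same scores.

Every stage is logged with its timing, and all randomness derives from the
configured seed, so identical configurations give identical outputs.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .config import PipelineConfig
from .evaluation import (
    EvaluationReport,
    EvaluationSplit,
    assert_no_leakage,
    combine_metrics,
    evaluate_causal_vs_noncausal,
    evaluate_causal_vs_nondisease,
    independent_split,
    make_folds,
)
from .imputation import (
    MIN_EDGES_FOR_IMPUTATION,
    BinaryNetwork,
    ImputedNetwork,
    binarize,
    embed_graph,
    impute_association_network,
    impute_links,
)
from .propagation import run_metric
from .semantics import disease_similarity
from .similarity import (
    binary_profile_similarity,
    continuous_similarity,
    gip_kernel,
    normalize_expression,
    sequence_similarity,
)
from .types import (
    AssociationMatrix,
    DiseaseDAG,
    MirnaProfileSet,
    ScoreMatrix,
    SimilarityMatrix,
    SIMILARITY_METRICS,
)

log = logging.getLogger("mdcapnet")

__all__ = ["DataBundle", "PipelineResult", "compute_similarities", "run_pipeline",
           "cross_validate"]

Pair = Tuple[str, str]


@dataclass
class DataBundle:
    profiles: MirnaProfileSet
    dag: DiseaseDAG
    associations: AssociationMatrix
    noncausal: List[Pair] = field(default_factory=list)


@dataclass
class PipelineResult:
    scores: ScoreMatrix
    per_metric: Dict[str, ScoreMatrix]
    report_nondisease: EvaluationReport
    report_noncausal: Optional[EvaluationReport]
    split: EvaluationSplit
    train_hash: str
    imputation_summary: Dict[str, Dict[str, float]]
    config: PipelineConfig


def _child_seed(base: int, k: int) -> int:
    return int(np.random.SeedSequence([base, k]).generate_state(1)[0] % (2**31))


def compute_similarities(
    profiles: MirnaProfileSet,
    train_md: AssociationMatrix,
    config: PipelineConfig,
) -> Dict[str, SimilarityMatrix]:
    """The six miRNA similarity matrices, each over the ids it covers."""
    sims: Dict[str, SimilarityMatrix] = {}
    t0 = time.perf_counter()
    sims["seq"] = sequence_similarity(profiles, config.sequence_weights)
    sims["tf"] = binary_profile_similarity(profiles, "tf")
    sims["gene"] = binary_profile_similarity(profiles, "target")
    if profiles.expression_profile:
        normalized = MirnaProfileSet(
            mirna_ids=list(profiles.mirna_ids),
            expression_profile=normalize_expression(profiles.expression_profile),
        )
        sims["expr"] = continuous_similarity(normalized, "expression")
    sims["pathway"] = continuous_similarity(profiles, "pathway")
    sims["gip"] = gip_kernel(train_md, axis="mirna")
    log.info("similarity stage: %d metrics in %.2fs [%s]", len(sims),
             time.perf_counter() - t0,
             ", ".join(f"{m}:{sims[m].values.shape[0]}x{sims[m].values.shape[0]}"
                       for m in sims))
    return sims


def _expand_network(net: BinaryNetwork, universe: List[str]) -> BinaryNetwork:
    """Embed a covered-subset similarity network into the full miRNA universe;
    uncovered miRNAs become isolated nodes."""
    if list(net.row_ids) == list(universe):
        return net
    pos = {m: i for i, m in enumerate(universe)}
    adj = np.zeros((len(universe), len(universe)))
    idx = np.array([pos[m] for m in net.row_ids])
    adj[np.ix_(idx, idx)] = net.adjacency
    return BinaryNetwork(adj, list(universe), None, net.origin, net.threshold_used)


def _relink_similarity(
    net: BinaryNetwork, config: PipelineConfig, seed: int
) -> ImputedNetwork:
    if not config.imputation_enabled or net.n_edges() < MIN_EDGES_FOR_IMPUTATION:
        if config.imputation_enabled:
            log.warning("similarity network too sparse (%d edges); not re-linked",
                        net.n_edges())
        return ImputedNetwork(net, [], {"skipped": 1.0})
    emb = embed_graph(net, config.embedding, seed)
    return impute_links(net, emb, config.link_probability, seed)


def run_pipeline(
    config: PipelineConfig,
    bundle: DataBundle,
    split: Optional[EvaluationSplit] = None,
) -> PipelineResult:
    """Execute the full pipeline on one train/test split (default: a fresh
    independent split of the known causal pairs)."""
    md = bundle.associations
    base_seed = config.evaluation.random_seed
    if split is None:
        split = independent_split(md, config.evaluation.test_fraction, base_seed)

    # --- training matrix: test positives removed before anything else
    t0 = time.perf_counter()
    train_md = md.copy()
    m_idx = {m: i for i, m in enumerate(md.mirna_ids)}
    d_idx = {d: j for j, d in enumerate(md.disease_ids)}
    for m, d in split.test_positives:
        train_md.values[m_idx[m], d_idx[d]] = 0.0
    train_hash = assert_no_leakage(train_md, split.test_positives)
    log.info("split fold=%d: %d train / %d test positives (train hash %s)",
             split.fold_id, len(split.train_positives), len(split.test_positives),
             train_hash[:12])

    # --- similarities (GIP from the training matrix only)
    sims = compute_similarities(bundle.profiles, train_md, config)
    ds = disease_similarity(bundle.dag, config.delta, ids=list(md.disease_ids))

    # --- binarize + impute
    universe = list(md.mirna_ids)
    nets: Dict[str, ImputedNetwork] = {}
    coverage: Dict[str, List[str]] = {}
    summaries: Dict[str, Dict[str, float]] = {}
    for k, metric in enumerate(SIMILARITY_METRICS):
        if metric not in sims:
            continue
        xi = config.binarization_thresholds[metric]
        bn = _expand_network(binarize(sims[metric], xi), universe)
        t1 = time.perf_counter()
        imp = _relink_similarity(bn, config, _child_seed(base_seed, k))
        nets[metric] = imp
        coverage[metric] = list(sims[metric].ids)
        summaries[metric] = dict(imp.summary)
        log.info("metric %s: xi=%.2f, %d edges (+%d imputed) in %.2fs", metric, xi,
                 bn.n_edges(), len(imp.imputed_edges), time.perf_counter() - t1)

    t1 = time.perf_counter()
    if config.imputation_enabled and int(train_md.values.sum()) >= MIN_EDGES_FOR_IMPUTATION:
        md_net = impute_association_network(
            train_md, config.embedding, config.link_probability,
            _child_seed(base_seed, 97), holdout_mask=split.test_positives,
        )
    else:
        md_net = ImputedNetwork(
            BinaryNetwork(train_md.values.copy(), list(md.mirna_ids),
                          list(md.disease_ids), "association", None),
            [], {"skipped": 1.0},
        )
    for m, d, _ in md_net.imputed_edges:
        if (m, d) in set(split.test_positives):  # defensive; masked upstream
            raise AssertionError(f"imputed edge ({m}, {d}) is a held-out test pair")
    summaries["association"] = dict(md_net.summary)
    log.info("association network: %d observed (+%d imputed) in %.2fs",
             int(train_md.values.sum()), len(md_net.imputed_edges),
             time.perf_counter() - t1)

    # --- per-metric propagation and fusion
    t1 = time.perf_counter()
    per_metric: Dict[str, ScoreMatrix] = {}
    for metric, imp in nets.items():
        per_metric[metric] = run_metric(imp, ds, md_net, config.solver, metric)
    scores = combine_metrics(per_metric, config.fusion_weights,
                             coverage=coverage, renormalize=True)
    log.info("propagation + fusion: %d metrics in %.2fs", len(per_metric),
             time.perf_counter() - t1)

    # --- evaluation on held-out pairs, same scores for both tasks
    known = set(md.positive_pairs()) | set(bundle.noncausal)
    report_nd = evaluate_causal_vs_nondisease(
        scores, split, known, config.evaluation.negative_ratio,
        seed=_child_seed(base_seed, 211),
    )
    report_nc = None
    if bundle.noncausal:
        report_nc = evaluate_causal_vs_noncausal(
            scores, split.test_positives, bundle.noncausal
        )
    log.info("pipeline done in %.2fs: causal-vs-non-disease AUROC %.3f%s",
             time.perf_counter() - t0, report_nd.auroc,
             f", causal-vs-non-causal AUROC {report_nc.auroc:.3f}" if report_nc else "")
    return PipelineResult(scores, per_metric, report_nd, report_nc, split,
                          train_hash, summaries, config)


def cross_validate(
    config: PipelineConfig, bundle: DataBundle, k: Optional[int] = None
) -> Dict[str, object]:
    """k-fold cross-validation over the known causal pairs.

    Returns per-fold AUROCs, their mean, and a pooled AUROC over the union
    of all folds' scored test pairs (both conventions are reported).
    """
    from .evaluation import auroc as _auroc

    k = k or config.evaluation.folds
    folds = make_folds(bundle.associations, k, config.evaluation.random_seed)
    fold_aurocs: List[float] = []
    pooled: List[Tuple[float, int]] = []
    results: List[PipelineResult] = []
    for split in folds:
        res = run_pipeline(config, bundle, split)
        results.append(res)
        fold_aurocs.append(res.report_nondisease.auroc)
        # pooled (score, label) pairs: same negatives the report used
        from .evaluation import _pair_scores, sample_nondisease_pairs

        known = set(bundle.associations.positive_pairs()) | set(bundle.noncausal)
        negs = sample_nondisease_pairs(
            res.scores, known,
            None if config.evaluation.negative_ratio is None
            else config.evaluation.negative_ratio * len(split.test_positives),
            _child_seed(config.evaluation.random_seed, 211),
        )
        pooled += [(s, 1) for s in _pair_scores(res.scores, split.test_positives)]
        pooled += [(s, 0) for s in _pair_scores(res.scores, negs)]
    return {
        "fold_aurocs": fold_aurocs,
        "mean_auroc": float(np.mean(fold_aurocs)),
        "pooled_auroc": _auroc(pooled),
        "results": results,
    }
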