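"""Evaluation protocol: folds, AUROC, rank-sum, fusion, leakage guards."""

import itertools

import numpy as np
import pytest

from mdcapnet.evaluation import (
    EvaluationSplit,
    assert_no_leakage,
    auroc,
    combine_metrics,
    evaluate_causal_vs_noncausal,
    evaluate_causal_vs_nondisease,
    grid_search_weights,
    independent_split,
    make_folds,
    wilcoxon_rank_sum,
)
from mdcapnet.types import AssociationMatrix, ScoreMatrix


def brute_force_auroc(scored):
    wins = 0.0
    pos = [s for s, l in scored if l == 1]
    neg = [s for s, l in scored if l == 0]
    for p in pos:
        for n in neg:
            wins += 1.0 if p > n else (0.5 if p == n else 0.0)
    return wins / (len(pos) * len(neg))


class TestAuroc:
    def test_perfect_separation(self):
        assert auroc([(0.9, 1), (0.8, 1), (0.2, 0)]) == 1.0

    def test_all_tied_gives_half(self):
        assert auroc([(0.5, 1), (0.5, 0), (0.5, 1), (0.5, 0)]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auroc([(0.5, 1), (0.3, 1)])

    def test_matches_pair_counting_with_and_without_ties(self):
        rng = np.random.default_rng(12)
        for _ in range(200):
            n = int(rng.integers(2, 9))
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            scores = rng.choice([0.1, 0.4, 0.4, 0.7, 0.9], size=n)
            scored = list(zip(scores.tolist(), labels.tolist()))
            assert auroc(scored) == pytest.approx(brute_force_auroc(scored))


def exact_ranksum_p(a, b):
    """Exact two-sided p by enumerating all group assignments (no ties)."""
    pooled = np.concatenate([a, b])
    na = len(a)
    u_obs = sum(1.0 for x in a for y in b if x > y)
    n1n2 = na * len(b)
    u_big = max(u_obs, n1n2 - u_obs)
    count = total = 0
    for comb in itertools.combinations(range(len(pooled)), na):
        grp = pooled[list(comb)]
        rest = np.delete(pooled, list(comb))
        u = sum(1.0 for x in grp for y in rest if x > y)
        if max(u, n1n2 - u) >= u_big:
            count += 1
        total += 1
    return min(1.0, count / total)


class TestWilcoxonRankSum:
    def test_known_exact_p(self):
        _, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1)

    def test_identical_groups_p_one(self, caplog):
        with caplog.at_level("WARNING", logger="mdcapnet"):
            _, p = wilcoxon_rank_sum([1.0, 1.0], [1.0, 1.0])
        assert p == 1.0

    def test_large_shift_highly_significant(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 300)
        b = rng.normal(5, 1, 300)
        _, p = wilcoxon_rank_sum(b, a)
        assert p < 1e-6

    def test_matches_exact_enumeration_small_samples(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            na, nb = int(rng.integers(2, 7)), int(rng.integers(2, 7))
            a = rng.normal(0, 1, na)
            b = rng.normal(0.5, 1, nb)
            _, p = wilcoxon_rank_sum(a, b)
            assert p == pytest.approx(exact_ranksum_p(a, b), abs=1e-12)

    def test_null_pvalues_roughly_uniform(self):
        """Calibration: under H0 the p-value distribution is near uniform."""
        rng = np.random.default_rng(42)
        pvals = []
        for _ in range(200):
            a = rng.normal(0, 1, 12)
            b = rng.normal(0, 1, 12)
            pvals.append(wilcoxon_rank_sum(a, b)[1])
        pvals = np.sort(pvals)
        ks = np.max(np.abs(pvals - (np.arange(1, 201) / 200)))
        assert ks < 0.1


class TestFolds:
    @staticmethod
    def md_with(n_pos):
        values = np.zeros((n_pos, 2))
        values[:, 0] = 1
        return AssociationMatrix(values, [f"m{i}" for i in range(n_pos)],
                                 ["d0", "d1"])

    def test_singleton_folds(self):
        folds = make_folds(self.md_with(10), 10, seed=0)
        assert all(len(f.test_positives) == 1 for f in folds)

    def test_sizes_within_one(self):
        folds = make_folds(self.md_with(11), 10, seed=0)
        sizes = sorted(len(f.test_positives) for f in folds)
        assert sizes == [1] * 9 + [2]

    def test_partition_covers_all_positives_once(self):
        md = self.md_with(13)
        folds = make_folds(md, 5, seed=3)
        seen = [p for f in folds for p in f.test_positives]
        assert sorted(seen) == sorted(md.positive_pairs())

    def test_deterministic_given_seed(self):
        f1 = make_folds(self.md_with(9), 3, seed=5)
        f2 = make_folds(self.md_with(9), 3, seed=5)
        assert [f.test_positives for f in f1] == [f.test_positives for f in f2]

    def test_too_many_folds_rejected(self):
        with pytest.raises(ValueError):
            make_folds(self.md_with(3), 10, seed=0)

    def test_independent_split_fraction(self):
        split = independent_split(self.md_with(10), 0.2, seed=1)
        assert len(split.test_positives) == 2
        assert len(split.train_positives) == 8


def perfect_scores(md):
    return ScoreMatrix(md.values.copy(), list(md.mirna_ids), list(md.disease_ids))


class TestTaskEvaluations:
    @staticmethod
    def setup_case():
        rng = np.random.default_rng(8)
        values = (rng.random((12, 10)) < 0.25).astype(float)
        values[0, 0] = 1
        md = AssociationMatrix(values, [f"m{i}" for i in range(12)],
                               [f"d{j}" for j in range(10)])
        return md

    def test_perfect_oracle_reaches_auroc_one(self):
        md = self.setup_case()
        positives = md.positive_pairs()
        split = EvaluationSplit(positives[:-4], positives[-4:], 0, seed=1)
        rep = evaluate_causal_vs_nondisease(perfect_scores(md), split,
                                            positives)
        assert rep.auroc == 1.0
        assert rep.roc_fpr[0] == 0.0 and rep.roc_tpr[-1] == 1.0

    def test_negative_ratio_controls_sample_size(self):
        md = self.setup_case()
        positives = md.positive_pairs()
        split = EvaluationSplit(positives[:-4], positives[-4:], 0, seed=1)
        rep1 = evaluate_causal_vs_nondisease(perfect_scores(md), split,
                                             positives, negative_ratio=1)
        rep5 = evaluate_causal_vs_nondisease(perfect_scores(md), split,
                                             positives, negative_ratio=5)
        assert rep1.n_negatives == 4 and rep5.n_negatives == 20
        assert rep1.auroc == rep5.auroc == 1.0

    def test_random_scores_near_half(self):
        md = self.setup_case()
        positives = md.positive_pairs()
        aurocs = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            sm = ScoreMatrix(rng.random(md.values.shape), list(md.mirna_ids),
                             list(md.disease_ids))
            split = EvaluationSplit(positives[:-15], positives[-15:], 0, seed=seed)
            aurocs.append(
                evaluate_causal_vs_nondisease(sm, split, positives).auroc)
        assert abs(np.mean(aurocs) - 0.5) < 0.1

    def test_causal_vs_noncausal_with_separated_scores(self):
        md = self.setup_case()
        rep = evaluate_causal_vs_noncausal(
            perfect_scores(md), md.positive_pairs()[:5], [("m0", "d9"), ("m1", "d9")])
        assert rep.auroc == 1.0
        assert rep.ranksum_pvalue is not None

    def test_empty_group_rejected(self):
        md = self.setup_case()
        with pytest.raises(ValueError):
            evaluate_causal_vs_noncausal(perfect_scores(md), [], [("m0", "d9")])


class TestCombineMetrics:
    @staticmethod
    def make_scores(values):
        return ScoreMatrix(np.asarray(values, float), ["m1", "m2"], ["d1"])

    def test_convexity_identical_inputs(self):
        sm = self.make_scores([[0.3], [0.7]])
        weights = {"seq": 0.15, "expr": 0.1, "gip": 0.05, "pathway": 0.25,
                   "gene": 0.2, "tf": 0.25}
        out = combine_metrics({m: sm for m in weights}, weights)
        np.testing.assert_allclose(out.values, sm.values)

    def test_single_nonzero_metric_scaled_by_its_weight(self):
        weights = {"seq": 0.15, "expr": 0.1, "gip": 0.05, "pathway": 0.25,
                   "gene": 0.2, "tf": 0.25}
        scores = {m: self.make_scores([[0.0], [0.0]]) for m in weights}
        scores["pathway"] = self.make_scores([[1.0], [1.0]])
        out = combine_metrics(scores, weights)
        np.testing.assert_allclose(out.values, 0.25)

    def test_degenerate_weights_select_one_metric(self):
        a = self.make_scores([[0.9], [0.1]])
        b = self.make_scores([[0.2], [0.2]])
        out = combine_metrics({"seq": a, "tf": b}, {"seq": 1.0, "tf": 0.0})
        np.testing.assert_allclose(out.values, a.values)

    def test_missing_metric_needs_renormalize_flag(self):
        a = self.make_scores([[0.9], [0.1]])
        with pytest.raises(ValueError, match="renormalize"):
            combine_metrics({"seq": a}, {"seq": 0.5, "tf": 0.5})
        out = combine_metrics({"seq": a}, {"seq": 0.5, "tf": 0.5},
                              renormalize=True)
        np.testing.assert_allclose(out.values, a.values)

    def test_coverage_renormalizes_per_row(self):
        a = self.make_scores([[0.8], [0.8]])
        b = self.make_scores([[0.4], [0.4]])
        out = combine_metrics({"seq": a, "tf": b}, {"seq": 0.5, "tf": 0.5},
                              coverage={"seq": ["m1", "m2"], "tf": ["m1"]})
        assert out.values[0, 0] == pytest.approx(0.6)  # both metrics
        assert out.values[1, 0] == pytest.approx(0.8)  # seq only, renormalized

    def test_preserves_entrywise_envelope(self):
        rng = np.random.default_rng(1)
        mats = {m: self.make_scores(rng.random((2, 1))) for m in ("seq", "tf", "gip")}
        w = {"seq": 0.3, "tf": 0.3, "gip": 0.4}
        out = combine_metrics(mats, w)
        stack = np.stack([mats[m].values for m in mats])
        assert (out.values >= stack.min(axis=0) - 1e-12).all()
        assert (out.values <= stack.max(axis=0) + 1e-12).all()


class TestGridSearch:
    @staticmethod
    def two_metric_case():
        rng = np.random.default_rng(3)
        md = AssociationMatrix((rng.random((10, 8)) < 0.3).astype(float),
                               [f"m{i}" for i in range(10)],
                               [f"d{j}" for j in range(8)])
        # narrow margin: any admixture of noise breaks perfect separation
        perfect = ScoreMatrix(0.5 + 0.1 * md.values, list(md.mirna_ids),
                              list(md.disease_ids))
        noise = ScoreMatrix(rng.random(md.values.shape), list(md.mirna_ids),
                            list(md.disease_ids))
        positives = md.positive_pairs()
        zeros = np.argwhere(md.values == 0)
        negatives = [(md.mirna_ids[i], md.disease_ids[j]) for i, j in zeros[:30]]
        return perfect, noise, positives, negatives

    def test_perfect_metric_gets_full_weight(self):
        perfect, noise, pos, neg = self.two_metric_case()
        w = grid_search_weights({"seq": perfect, "tf": noise}, pos, neg, step=0.25)
        assert w["seq"] == 1.0 and w["tf"] == 0.0

    def test_reproducible(self):
        perfect, noise, pos, neg = self.two_metric_case()
        w1 = grid_search_weights({"seq": perfect, "tf": noise}, pos, neg, step=0.5)
        w2 = grid_search_weights({"seq": perfect, "tf": noise}, pos, neg, step=0.5)
        assert w1 == w2

    def test_step_must_divide_one(self):
        perfect, noise, pos, neg = self.two_metric_case()
        with pytest.raises(ValueError):
            grid_search_weights({"seq": perfect, "tf": noise}, pos, neg, step=0.3)


class TestLeakageGuard:
    def test_clean_split_returns_hash(self, tiny_md):
        h = assert_no_leakage(tiny_md, [("m1", "d2")])  # (m1,d2) is 0 in MD
        assert len(h) == 64

    def test_test_pair_in_training_matrix_raises(self, tiny_md):
        with pytest.raises(AssertionError, match="leakage"):
            assert_no_leakage(tiny_md, [("m1", "d1")])
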