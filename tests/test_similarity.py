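"""miRNA similarity metrics against independent oracles and closed forms."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mdcapnet.similarity import (
    binary_profile_similarity,
    continuous_similarity,
    gip_kernel,
    levenshtein_similarity,
    normalize_expression,
    pathway_features,
    sequence_similarity,
    tanimoto_similarity,
)
from mdcapnet.types import AssociationMatrix, MirnaProfileSet


def dp_levenshtein(s1: str, s2: str) -> int:
    """Quadratic dynamic-programming edit distance (independent oracle)."""
    prev = list(range(len(s2) + 1))
    for i, a in enumerate(s1, 1):
        cur = [i]
        for j, b in enumerate(s2, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (a != b)))
        prev = cur
    return prev[-1]


class TestLevenshtein:
    @pytest.mark.parametrize("s1,s2,expected", [
        ("ACGU", "ACGU", 1.0),
        ("AAAA", "CCCC", 0.5),
        ("ACGU", "ACG", 6 / 7),
    ])
    def test_known_values(self, s1, s2, expected):
        assert levenshtein_similarity(s1, s2) == pytest.approx(expected, abs=1e-15)

    def test_empty_string_rejected(self):
        with pytest.raises(ValueError):
            levenshtein_similarity("", "ACGU")

    @settings(max_examples=100, derandomize=True)
    @given(st.text(alphabet="ACGU", min_size=1, max_size=40),
           st.text(alphabet="ACGU", min_size=1, max_size=40))
    def test_matches_dp_oracle_and_is_symmetric(self, s1, s2):
        sim = levenshtein_similarity(s1, s2)
        assert sim == pytest.approx(1 - dp_levenshtein(s1, s2) / (len(s1) + len(s2)))
        assert sim == levenshtein_similarity(s2, s1)
        assert 0 <= sim <= 1

    @settings(max_examples=100, derandomize=True)
    @given(st.integers(1, 30), st.integers(0, 10**9))
    def test_equal_length_lower_bound_half(self, length, seed):
        rng = np.random.default_rng(seed)
        a = "".join(np.array(list("ACGU"))[rng.integers(0, 4, length)])
        b = "".join(np.array(list("ACGU"))[rng.integers(0, 4, length)])
        assert levenshtein_similarity(a, b) >= 0.5


class TestSequenceSimilarity:
    def test_identical_mirnas_score_one(self):
        p = MirnaProfileSet(
            mirna_ids=["a", "b"],
            precursor_seq={"a": "ACGU", "b": "ACGU"},
            mature_seq={"a": "ACG", "b": "ACG"},
            seed_seq={"a": "CG", "b": "CG"})
        sm = sequence_similarity(p)
        assert sm.values[0, 1] == 1.0

    def test_weighted_sum_of_levels(self, tiny_profiles):
        sm = sequence_similarity(tiny_profiles)
        expected = (
            0.80 * levenshtein_similarity("ACGUACGUAC", "UUUUGGGGCC")
            + 0.15 * levenshtein_similarity("ACGUACG", "GGGGCCC")
            + 0.05 * levenshtein_similarity("CGUACG", "GGGCCC"))
        assert sm.values[0, 2] == pytest.approx(expected)

    def test_degenerate_weights_give_single_level(self, tiny_profiles):
        sm = sequence_similarity(
            tiny_profiles, {"precursor": 1.0, "mature": 0.0, "seed": 0.0})
        expected = levenshtein_similarity("ACGUACGUAC", "UUUUGGGGCC")
        assert sm.values[0, 2] == pytest.approx(expected)
        assert sm.values[0, 1] == 1.0  # identical precursors

    def test_missing_level_rejected(self):
        p = MirnaProfileSet(mirna_ids=["a", "b"],
                            precursor_seq={"a": "ACGU", "b": "ACGU"},
                            mature_seq={"a": "ACG", "b": "ACG"},
                            seed_seq={"a": "CG"})
        with pytest.raises(ValueError, match="b"):
            sequence_similarity(p)


class TestBinaryProfileSimilarity:
    @pytest.mark.parametrize("v1,v2,expected", [
        ([1, 0, 1], [1, 0, 1], 1.0),
        ([1, 1, 1], [0, 0, 0], 0.5),
        ([1, 1, 0], [1, 0, 0], 5 / 6),
    ])
    def test_known_values(self, v1, v2, expected):
        p = MirnaProfileSet(mirna_ids=["a", "b"],
                            tf_profile={"a": np.array(v1, float),
                                        "b": np.array(v2, float)})
        sm = binary_profile_similarity(p, "tf")
        assert sm.values[0, 1] == pytest.approx(expected)
        assert sm.metric == "tf"

    def test_target_maps_to_gene_metric(self, tiny_profiles):
        sm = binary_profile_similarity(tiny_profiles, "target")
        assert sm.metric == "gene"

    def test_equal_length_scores_at_least_half(self, tiny_profiles):
        sm = binary_profile_similarity(tiny_profiles, "tf")
        assert sm.values.min() >= 0.5


class TestTanimoto:
    def test_self_similarity_one(self):
        assert tanimoto_similarity([1.0, 2.0], [1.0, 2.0]) == 1.0

    def test_orthogonal_zero(self):
        assert tanimoto_similarity([1.0, 0.0], [0.0, 1.0]) == 0.0

    def test_binary_example(self):
        assert tanimoto_similarity([1, 1, 0], [1, 0, 0]) == pytest.approx(0.5)

    def test_both_zero_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            tanimoto_similarity([0.0, 0.0], [0.0, 0.0])

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(st.booleans(), min_size=1, max_size=12),
           st.lists(st.booleans(), min_size=1, max_size=12))
    def test_binary_vectors_equal_jaccard(self, a, b):
        n = max(len(a), len(b))
        a = a + [False] * (n - len(a))
        b = b + [False] * (n - len(b))
        if not (any(a) or any(b)):
            return
        sa = {i for i, x in enumerate(a) if x}
        sb = {i for i, x in enumerate(b) if x}
        jaccard = len(sa & sb) / len(sa | sb)
        got = tanimoto_similarity(np.array(a, float), np.array(b, float))
        assert got == pytest.approx(jaccard)


class TestContinuousSimilarity:
    def test_matrix_matches_pairwise_oracle(self, tiny_profiles):
        sm = continuous_similarity(tiny_profiles, "pathway")
        block = tiny_profiles.pathway_profile
        ids = sm.ids
        for i in range(3):
            for j in range(3):
                expected = 1.0 if i == j else tanimoto_similarity(
                    block[ids[i]], block[ids[j]])
                assert sm.values[i, j] == pytest.approx(expected)

    def test_all_zero_profile_named(self):
        p = MirnaProfileSet(mirna_ids=["a", "b"],
                            pathway_profile={"a": np.array([1.0]),
                                             "b": np.array([0.0])})
        with pytest.raises(ValueError, match="'b'"):
            continuous_similarity(p, "pathway")


class TestNormalizeExpression:
    def test_column_scaled_then_log1p(self):
        out = normalize_expression({"a": np.array([1.0]), "b": np.array([1.0])})
        assert out["a"][0] == pytest.approx(np.log1p(0.5))

    def test_invariant_to_column_rescaling(self):
        raw = {"a": np.array([1.0, 4.0]), "b": np.array([3.0, 2.0])}
        scaled = {m: v * np.array([10.0, 1.0]) for m, v in raw.items()}
        out1 = normalize_expression(raw)
        out2 = normalize_expression(scaled)
        for m in raw:
            np.testing.assert_allclose(out1[m], out2[m])

    def test_zero_column_dropped(self, caplog):
        with caplog.at_level("WARNING", logger="mdcapnet"):
            out = normalize_expression({"a": np.array([1.0, 0.0]),
                                        "b": np.array([1.0, 0.0])})
        assert out["a"].size == 1
        assert "all-zero" in caplog.text


class TestPathwayFeatures:
    def test_retention_needs_three_significant(self):
        pvals = {("m1", "pw"): 0.01, ("m2", "pw"): 0.01}
        assert all(v.size == 0 for v in pathway_features(pvals).values())

    def test_three_significant_retained_with_neglog10(self):
        pvals = {(f"m{i}", "pw"): 0.01 for i in range(3)}
        out = pathway_features(pvals)
        assert out["m0"][0] == pytest.approx(2.0)

    def test_cap_at_twenty(self):
        pvals = {(f"m{i}", "pw"): 1e-30 for i in range(3)}
        assert pathway_features(pvals)["m0"][0] == 20.0

    def test_nonpositive_p_rejected(self):
        with pytest.raises(ValueError):
            pathway_features({("m1", "pw"): 0.0})


class TestGipKernel:
    def test_identical_rows_score_one(self):
        md = AssociationMatrix(np.array([[1.0, 0.0], [1.0, 0.0]]),
                               ["a", "b"], ["d1", "d2"])
        assert gip_kernel(md).values[0, 1] == pytest.approx(1.0)

    def test_identity_matrix_off_diagonal(self, ):
        md = AssociationMatrix(np.eye(2), ["a", "b"], ["d1", "d2"])
        assert gip_kernel(md).values[0, 1] == pytest.approx(np.exp(-2))

    def test_zero_row_against_unit_row(self):
        md = AssociationMatrix(np.array([[1.0, 0.0], [0.0, 0.0]]),
                               ["a", "b"], ["d1", "d2"])
        gm = gip_kernel(md)
        # mean profile norm 0.5 => gamma = 2; ||e1 - 0||^2 = 1
        assert gm.values[0, 1] == pytest.approx(np.exp(-2))
        assert gm.values[1, 1] == 1.0

    def test_all_zero_rejected(self):
        md = AssociationMatrix(np.zeros((2, 2)), ["a", "b"], ["d1", "d2"])
        with pytest.raises(ValueError, match="all-zero"):
            gip_kernel(md)

    def test_relabeling_equivariance(self):
        rng = np.random.default_rng(5)
        values = (rng.random((5, 4)) < 0.4).astype(float)
        values[0, 0] = 1.0
        ids = [f"m{i}" for i in range(5)]
        md = AssociationMatrix(values, ids, [f"d{j}" for j in range(4)])
        gm = gip_kernel(md).values
        perm = rng.permutation(5)
        md_p = AssociationMatrix(values[perm], [ids[i] for i in perm],
                                 [f"d{j}" for j in range(4)])
        gm_p = gip_kernel(md_p).values
        np.testing.assert_allclose(gm_p, gm[np.ix_(perm, perm)], atol=1e-12)


def test_all_metrics_satisfy_matrix_invariants(small_bundle):
    """Symmetry, unit diagonal, [0,1] range across all six metrics."""
    from mdcapnet.config import PipelineConfig
    from mdcapnet.pipeline import compute_similarities

    sims = compute_similarities(small_bundle.profiles, small_bundle.associations,
                                PipelineConfig())
    assert set(sims) == {"seq", "expr", "gip", "pathway", "gene", "tf"}
    for metric, sm in sims.items():
        assert np.abs(sm.values - sm.values.T).max() <= 1e-10, metric
        np.testing.assert_allclose(np.diagonal(sm.values), 1.0, err_msg=metric)
        assert sm.values.min() >= 0 and sm.values.max() <= 1, metric
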