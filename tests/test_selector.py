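"""Selector unit and property tests, anchored on an independent naive oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import sepselect as ss
from sepselect.errors import DomainError
from sepselect.io_expression import ClassMap, ExpressionMatrix
from sepselect.selector import abs_deviations, class_means, score_feature


def random_instance(rng, n_max=20, m_max=50, c_max=4):
    c = rng.integers(2, c_max + 1)
    # at least one sample per class
    sizes = rng.multinomial(rng.integers(c, n_max + 1) - c, np.ones(c) / c) + 1
    codes = np.repeat(np.arange(1, c + 1), sizes)
    n = codes.size
    m = rng.integers(1, m_max + 1)
    values = rng.normal(0.0, rng.uniform(0.5, 10.0), size=(n, m))
    return values, codes


def as_matrix(values, codes):
    names = tuple(f"C{c}" for c in sorted(set(codes.tolist())))
    labels = np.array([f"C{c}" for c in codes], dtype=object)
    return ExpressionMatrix(
        values=values,
        sample_ids=[f"s{i}" for i in range(values.shape[0])],
        gene_ids=[f"g{j}" for j in range(values.shape[1])],
        labels=labels,
        class_map=ClassMap(names),
    )


class TestSmallOperations:
    def test_class_means_hand_example(self):
        values = np.array([1.0, 3.0, 10.0, 10.0, 10.0])
        codes = np.array([1, 1, 2, 2, 2])
        np.testing.assert_array_equal(class_means(values, codes), [2.0, 10.0])

    def test_class_means_constant_and_singleton(self):
        np.testing.assert_array_equal(
            class_means(np.array([4.0, 4.0, 4.0]), np.array([1, 1, 2])), [4.0, 4.0]
        )
        np.testing.assert_array_equal(
            class_means(np.array([7.0, 2.0]), np.array([1, 2])), [7.0, 2.0]
        )

    def test_abs_deviations_hand_example(self):
        values = np.array([1.0, 3.0])
        codes = np.array([1, 1])
        with pytest.raises(DomainError):
            # a single class is not a valid partition for the score
            score_feature(values, codes)
        # deviations themselves for two classes
        values = np.array([1.0, 3.0, 5.0, 5.0])
        codes = np.array([1, 1, 2, 2])
        np.testing.assert_array_equal(
            abs_deviations(values, codes), [1.0, 1.0, 0.0, 0.0]
        )

    def test_abs_deviations_invariant_to_per_class_shift(self):
        rng = np.random.default_rng(0)
        values = rng.normal(size=10)
        codes = np.array([1] * 5 + [2] * 5)
        shifted = values + np.where(codes == 1, 100.0, -3.0)
        np.testing.assert_allclose(
            abs_deviations(values, codes), abs_deviations(shifted, codes), atol=1e-12
        )

    def test_score_feature_enumerated_example(self):
        # class 1 deviations {0.5, 1.0} -> max 1.0; class 2 {0.2, 0.3} -> max 0.3
        # built from values whose deviations are exactly those
        values = np.array([2.25, 1.25, 3.05, 2.55])  # means 1.75 and 2.80
        codes = np.array([1, 1, 2, 2])
        b = abs_deviations(values, codes)
        np.testing.assert_allclose(np.sort(b[:2]), [0.5, 0.5])
        values = np.array([1.0, 2.0, 0.0, 10.05, 10.25, 9.75])
        codes = np.array([1, 1, 1, 2, 2, 2])
        # class1 mean 1 -> devs 0,1,1 max 1.0; class2 mean 10.0166.. -> max ~0.266
        d = score_feature(values, codes)
        assert d == pytest.approx(min(1.0, np.abs([10.05, 10.25, 9.75] - np.mean([10.05, 10.25, 9.75])).max()))

    def test_constant_within_every_class_scores_zero(self):
        values = np.array([3.0, 3.0, -1.0, -1.0])
        codes = np.array([1, 1, 2, 2])
        assert score_feature(values, codes) == 0.0


class TestOracleEquivalence:
    def test_matches_naive_oracle_on_many_random_instances(self, naive_scorer):
        rng = np.random.default_rng(12345)
        for _ in range(50):
            values, codes = random_instance(rng)
            matrix = as_matrix(values, codes)
            np.testing.assert_array_equal(
                ss.score_all(matrix), naive_scorer(values, codes)
            )

    def test_matches_oracle_on_larger_simulation(self, sim_default, naive_scorer):
        matrix, _ = sim_default
        sub = matrix.subset_genes(range(0, 200))
        np.testing.assert_allclose(
            ss.score_all(sub),
            naive_scorer(sub.values, sub.label_codes),
            atol=1e-12,
        )

    def test_score_all_equals_columnwise_score_feature(self, anchor):
        codes = anchor.label_codes
        per_column = [
            score_feature(anchor.values[:, j], codes) for j in range(anchor.n_genes)
        ]
        np.testing.assert_array_equal(ss.score_all(anchor), per_column)


class TestScoreProperties:
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_nonnegative_and_homogeneous(self, seed):
        rng = np.random.default_rng(seed)
        values, codes = random_instance(rng, n_max=12, m_max=8)
        scores = ss.score_all(as_matrix(values, codes))
        assert (scores >= 0).all()
        alpha = float(rng.normal()) or 1.0
        scaled = ss.score_all(as_matrix(alpha * values, codes))
        np.testing.assert_allclose(scaled, abs(alpha) * scores, rtol=1e-10, atol=1e-12)

    def test_sample_permutation_invariance(self, sim_small):
        matrix, _ = sim_small
        rng = np.random.default_rng(9)
        perm = rng.permutation(matrix.n_samples)
        np.testing.assert_allclose(
            ss.score_all(matrix.subset_samples(perm)),
            ss.score_all(matrix),
            atol=1e-12,
        )

    def test_gene_permutation_equivariance(self, anchor):
        perm = np.array([2, 0, 3, 1])
        np.testing.assert_array_equal(
            ss.score_all(anchor.subset_genes(perm)), ss.score_all(anchor)[perm]
        )


class TestRankAndSelect:
    def test_descending_enumeration(self):
        res = ss.rank_and_select(np.array([3.0, 1.0, 2.0]), k=2)
        np.testing.assert_array_equal(res.selected, [0, 2])
        np.testing.assert_array_equal(res.ranking, [0, 2, 1])

    def test_ascending_direction(self):
        res = ss.rank_and_select(np.array([3.0, 1.0, 2.0]), k=2, direction="ascending")
        np.testing.assert_array_equal(res.selected, [1, 2])

    def test_ties_break_by_ascending_gene_index(self):
        res = ss.rank_and_select(np.array([1.0, 1.0, 1.0]), k=3)
        np.testing.assert_array_equal(res.selected, [0, 1, 2])

    def test_k_larger_than_m_truncates(self):
        res = ss.rank_and_select(np.array([1.0, 2.0]), k=25)
        assert len(res.selected) == 2

    @pytest.mark.parametrize("bad_k", [0, -1])
    def test_k_below_one_rejected(self, bad_k):
        with pytest.raises(DomainError):
            ss.rank_and_select(np.array([1.0]), k=bad_k)

    def test_anchor_fixture_ranking(self, anchor):
        res = ss.select_features(anchor, k=4)
        from sepselect.synthetic_data import FIXTURE_RANKING, FIXTURE_SCORES

        np.testing.assert_array_equal(res.scores, FIXTURE_SCORES)
        np.testing.assert_array_equal(res.ranking, FIXTURE_RANKING)
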