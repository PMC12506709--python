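"""Index coefficients, EBV standardization, aggregate scores and ranking."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from sireval import (
    IndexInputs,
    build_index,
    index_weights,
    rank_and_select,
    standardize_ebv,
    total_score,
)
from sireval.errors import ConditioningError
from sireval.presets import ECONOMIC_WEIGHTS, TRAITS


class TestIndexWeights:
    def test_identity_matrices_return_economic_values(self):
        a = np.array([2.0, -1.0, 0.5])
        b = index_weights(IndexInputs(np.eye(3), np.eye(3), a))
        np.testing.assert_allclose(b, a)

    def test_p_equals_g_returns_economic_values(self):
        P = np.array([[2.0, 0.3], [0.3, 1.0]])
        a = np.array([1.0, -2.0])
        b = index_weights(IndexInputs(P, P, a))
        np.testing.assert_allclose(b, a, atol=1e-12)

    def test_two_trait_case_matches_hand_inversion(self):
        P = np.array([[4.0, 1.0], [1.0, 2.0]])
        G = np.array([[1.0, 0.5], [0.5, 1.0]])
        a = np.array([1.0, 1.0])
        # P^-1 = (1/7) [[2, -1], [-1, 4]]; G a = [1.5, 1.5]
        expected = np.array([[2, -1], [-1, 4]]) @ np.array([1.5, 1.5]) / 7.0
        np.testing.assert_allclose(index_weights(IndexInputs(P, G, a)), expected)

    def test_singular_p_reports_smallest_eigenvalue(self):
        P = np.array([[1.0, 1.0], [1.0, 1.0]])
        with pytest.raises(ConditioningError, match="eigenvalue"):
            index_weights(IndexInputs(P, np.eye(2), np.ones(2)))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_linear_in_economic_values(self, seed):
        rng = np.random.default_rng(seed)
        t = int(rng.integers(2, 6))
        L = rng.normal(size=(t, t))
        P = L @ L.T + t * np.eye(t)
        G = rng.normal(size=(t, t))
        G = (G + G.T) / 2
        a1, a2 = rng.normal(size=t), rng.normal(size=t)
        b12 = index_weights(IndexInputs(P, G, a1 + a2))
        b1 = index_weights(IndexInputs(P, G, a1))
        b2 = index_weights(IndexInputs(P, G, a2))
        np.testing.assert_allclose(b12, b1 + b2, atol=1e-8)


class TestStandardizeEbv:
    def test_population_sd_z_scores(self):
        ebvs = pd.DataFrame({"t": [-1.0, 0.0, 1.0]}, index=["x", "y", "z"])
        X = standardize_ebv(ebvs)
        np.testing.assert_allclose(
            X["t"].to_numpy(), [-1.224745, 0.0, 1.224745], atol=1e-6
        )

    def test_identical_ebvs_standardize_to_zero_with_warning(self):
        ebvs = pd.DataFrame({"t": [2.0, 2.0, 2.0]})
        with pytest.warns(UserWarning, match="zero EBV variance"):
            X = standardize_ebv(ebvs)
        assert (X["t"] == 0).all()

    def test_single_bull_rejected(self):
        with pytest.raises(ValueError):
            standardize_ebv(pd.DataFrame({"t": [1.0]}))

    def test_columns_are_zero_mean_unit_sd(self):
        rng = np.random.default_rng(8)
        ebvs = pd.DataFrame(rng.normal(5, 3, size=(20, 4)), columns=list("abcd"))
        X = standardize_ebv(ebvs)
        np.testing.assert_allclose(X.mean(), 0.0, atol=1e-12)
        np.testing.assert_allclose(X.std(ddof=0), 1.0, atol=1e-12)


class TestTotalScore:
    def test_zero_weights_zero_scores(self):
        X = pd.DataFrame(np.ones((3, 2)), columns=["a", "b"])
        assert (total_score(X, [0.0, 0.0]) == 0).all()

    def test_single_nonzero_weight_preserves_single_trait_ranking(self):
        rng = np.random.default_rng(1)
        ebvs = pd.DataFrame(
            rng.normal(size=(10, 3)), columns=list("abc"),
            index=[f"B{i:02d}" for i in range(10)],
        )
        X = standardize_ebv(ebvs)
        scores = total_score(X, [0.0, 5.0, 0.0])
        assert (
            scores.sort_values(ascending=False).index.tolist()
            == ebvs["b"].sort_values(ascending=False).index.tolist()
        )

    def test_economic_weight_vector_matches_brute_force_sum(self):
        rng = np.random.default_rng(2)
        ebvs = pd.DataFrame(
            rng.normal(size=(51, 8)), columns=TRAITS,
            index=[f"B{i:02d}" for i in range(51)],
        )
        X = standardize_ebv(ebvs)
        w = [ECONOMIC_WEIGHTS[t] for t in TRAITS]
        scores = total_score(X, w)
        brute = [
            sum(w[k] * X.iloc[i, k] for k in range(8)) for i in range(51)
        ]
        np.testing.assert_allclose(scores.to_numpy(), brute, atol=1e-10)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            total_score(pd.DataFrame(np.ones((2, 3))), [1.0, 2.0])


class TestRankAndSelect:
    def test_top_fifth_of_51_bulls_selects_11(self):
        scores = pd.Series(
            np.linspace(10, -10, 51), index=[f"B{i:02d}" for i in range(51)]
        )
        out = rank_and_select(scores, 0.20)
        assert int(out["selected"].sum()) == 11
        assert out["rank"].tolist() == list(range(1, 52))

    def test_half_of_ten(self):
        scores = pd.Series(range(10), index=[f"B{i}" for i in range(10)])
        assert int(rank_and_select(scores, 0.5)["selected"].sum()) == 5

    def test_ceiling_rule(self):
        scores = pd.Series([3.0, 2.0, 1.0])
        assert int(rank_and_select(scores, 0.34)["selected"].sum()) == math.ceil(
            0.34 * 3
        )

    def test_ties_resolved_by_identifier(self):
        scores = pd.Series([1.0, 1.0, 1.0, 1.0], index=["d", "b", "a", "c"])
        out = rank_and_select(scores, 0.5)
        assert out.index.tolist() == ["a", "b", "c", "d"]
        assert out.index[out["selected"]].tolist() == ["a", "b"]

    def test_invalid_fraction_and_empty_scores(self):
        with pytest.raises(ValueError):
            rank_and_select(pd.Series([1.0]), 0.0)
        with pytest.raises(ValueError):
            rank_and_select(pd.Series(dtype=float), 0.5)

    def test_ranks_are_a_permutation(self):
        rng = np.random.default_rng(4)
        scores = pd.Series(rng.normal(size=17), index=[f"B{i}" for i in range(17)])
        out = rank_and_select(scores, 0.3)
        assert sorted(out["rank"]) == list(range(1, 18))


class TestEndToEnd:
    def test_ranking_invariant_to_positive_weight_rescaling(self):
        rng = np.random.default_rng(5)
        ebvs = pd.DataFrame(
            rng.normal(size=(15, 4)), columns=list("wxyz"),
            index=[f"B{i:02d}" for i in range(15)],
        )
        w = np.array([1.0, -2.0, 0.5, 3.0])
        r1 = build_index(ebvs, weights=w).ranking
        r2 = build_index(ebvs, weights=7.3 * w).ranking
        assert r1.index.tolist() == r2.index.tolist()
        assert r1["rank"].tolist() == r2["rank"].tolist()

    def test_diagonal_matrices_one_hot_weights_reduce_to_single_trait(self):
        rng = np.random.default_rng(6)
        ebvs = pd.DataFrame(
            rng.normal(size=(12, 3)), columns=list("abc"),
            index=[f"B{i:02d}" for i in range(12)],
        )
        inputs = IndexInputs(np.diag([2.0, 3.0, 4.0]), np.diag([2.0, 3.0, 4.0]),
                             np.array([0.0, 1.0, 0.0]))
        res = build_index(ebvs, inputs=inputs)
        single = ebvs["b"].sort_values(ascending=False).index.tolist()
        assert res.ranking.index.tolist() == single
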