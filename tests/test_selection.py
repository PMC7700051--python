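from fractions import Fraction
from itertools import product
from math import comb

import numpy as np
import pytest

from amyloidkit.selection import (
    BinomialSelector,
    MRMDSelector,
    bd_rank,
    binomial_tail,
    feature_distance,
    incremental_subset_eval,
    mrmd_rank,
    pearson_relevance,
)


def exact_binomial_tail(N, n, q: Fraction) -> Fraction:
    """Rational-arithmetic upper binomial tail, the independent oracle."""
    return sum(
        Fraction(comb(N, k)) * q**k * (1 - q) ** (N - k) for k in range(n, N + 1)
    )


class TestPearsonRelevance:
    def test_feature_equal_to_labels_is_one(self):
        y = np.array([0, 0, 1, 1])
        X = np.column_stack([y.astype(float)])
        assert pearson_relevance(X, y, 0) == pytest.approx(1.0)

    def test_constant_feature_is_zero(self):
        X = np.full((4, 1), 3.7)
        assert pearson_relevance(X, np.array([0, 0, 1, 1]), 0) == 0.0

    def test_orthogonal_feature_is_zero(self):
        X = np.array([[1.0], [0.0], [1.0], [0.0]])
        assert pearson_relevance(X, np.array([0, 0, 1, 1]), 0) == pytest.approx(0.0)

    def test_sign_is_dropped(self):
        y = np.array([0, 0, 1, 1])
        X = np.column_stack([-y.astype(float)])
        assert pearson_relevance(X, y, 0) == pytest.approx(1.0)


class TestFeatureDistance:
    def test_identical_columns_have_zero_ed(self):
        col = np.array([0.0, 0.0, 1.0, 1.0])
        X = np.column_stack([col, col])
        assert feature_distance(X, 0, "ED") == pytest.approx(0.0)

    def test_hand_euclidean(self):
        X = np.column_stack([[0, 0, 1, 1], [1, 0, 1, 0]]).astype(float)
        assert feature_distance(X, 0, "ED") == pytest.approx(np.sqrt(2))

    def test_mean_over_other_features(self):
        f = np.array([0, 0, 1, 1.0])
        g = np.array([1, 0, 1, 0.0])
        X = np.column_stack([f, f, g])
        assert feature_distance(X, 0, "ED") == pytest.approx(np.sqrt(2) / 2)
        assert feature_distance(X, 2, "ED") == pytest.approx(np.sqrt(2))

    def test_zero_norm_column_contributes_zero_under_cos_tc(self):
        X = np.column_stack([[0, 0, 0, 0], [1, 0, 1, 0]]).astype(float)
        assert feature_distance(X, 1, "COS") == pytest.approx(0.0)
        assert feature_distance(X, 1, "TC") == pytest.approx(0.0)

    def test_cos_tc_match_definitions(self):
        rng = np.random.default_rng(3)
        X = rng.random((6, 4))
        for i in range(4):
            cos_d, tc_d = [], []
            for k in range(4):
                if k == i:
                    continue
                a, b = X[:, i], X[:, k]
                cos_d.append(1 - a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))
                tc_d.append(1 - a @ b / (a @ a + b @ b - a @ b))
            assert feature_distance(X, i, "COS") == pytest.approx(np.mean(cos_d))
            assert feature_distance(X, i, "TC") == pytest.approx(np.mean(tc_d))


class TestMRMDRank:
    def toy(self):
        y = np.array([0, 0, 1, 1])
        f = y.astype(float)
        g = np.array([1, 0, 1, 0.0])
        return np.column_stack([f, f, g]), y

    def test_toy_ranking_and_tie_break(self):
        X, y = self.toy()
        ranked = mrmd_rank(X, y, "ED")
        # duplicates of the label vector come first, in index order
        assert list(ranked.order) == [0, 1, 2]
        assert ranked.scores[0] == ranked.scores[1]

    def test_informative_feature_dominates_constants(self):
        y = np.array([0, 0, 1, 1])
        X = np.column_stack([np.ones(4), y.astype(float), np.full(4, 2.0)])
        ranked = mrmd_rank(X, y, "ED")
        assert ranked.order[0] == 1

    def test_mean_metric_recomposes_from_single_metrics(self):
        rng = np.random.default_rng(8)
        X = rng.random((10, 5))
        y = np.array([0, 1] * 5)
        d = X.shape[1]
        mr = np.array([pearson_relevance(X, y, i) for i in range(d)])
        md = np.mean(
            [[feature_distance(X, i, m) for i in range(d)] for m in ("ED", "COS", "TC")],
            axis=0,
        )

        def mm(v):
            return (v - v.min()) / (v.max() - v.min())

        expected = mm(mr) + mm(md)
        assert mrmd_rank(X, y, "MEAN").scores == pytest.approx(expected)

    def test_all_constant_features_error(self):
        with pytest.raises(ValueError):
            mrmd_rank(np.ones((4, 3)), np.array([0, 0, 1, 1]))

    def test_bad_metric_and_single_class_errors(self):
        X = np.random.default_rng(0).random((4, 3))
        with pytest.raises(ValueError):
            mrmd_rank(X, np.array([0, 0, 1, 1]), metric="L1")
        with pytest.raises(ValueError):
            mrmd_rank(X, np.zeros(4, dtype=int))

    def test_duplicate_never_beats_equal_relevance_larger_distance(self):
        """Redundancy penalty: duplicating a column cannot rank the duplicate
        above a feature with equal relevance but strictly larger mean distance."""
        y = np.array([0, 0, 1, 1])
        pool = [
            np.array([0, 0, 1, 1.0]),
            np.array([1, 0, 1, 0.0]),
            np.array([0.5, 0.5, 1, 1.0]),
            np.array([0, 1, 0, 1.0]),
        ]
        for cols in product(range(len(pool)), repeat=3):
            X = np.column_stack([pool[c] for c in cols] + [pool[cols[0]]])
            dup = X.shape[1] - 1
            ranked = mrmd_rank(X, y, "ED")
            mr = [pearson_relevance(X, y, i) for i in range(X.shape[1])]
            md = [feature_distance(X, i, "ED") for i in range(X.shape[1])]
            pos = {f: r for r, f in enumerate(ranked.order)}
            for i in range(dup):
                if mr[i] == pytest.approx(mr[dup]) and md[i] > md[dup] + 1e-12:
                    assert pos[i] < pos[dup]


class TestBinomialTail:
    @pytest.mark.parametrize(
        "N, n, q, expected",
        [
            (10, 9, 0.5, 11 / 1024),
            (10, 0, 0.5, 1.0),
            (10, 10, 0.5, 1 / 1024),
            (5, 3, 0.2, float(exact_binomial_tail(5, 3, Fraction(1, 5)))),
        ],
    )
    def test_examples(self, N, n, q, expected):
        assert binomial_tail(N, n, q) == pytest.approx(expected, abs=1e-12)

    def test_matches_exact_rational_oracle(self):
        for N in (1, 4, 9, 16, 20):
            for n in range(N + 1):
                for q in (Fraction(1, 4), Fraction(1, 2), Fraction(7, 10)):
                    got = binomial_tail(N, n, float(q))
                    assert got == pytest.approx(float(exact_binomial_tail(N, n, q)), abs=1e-12)

    def test_invalid_counts_error(self):
        with pytest.raises(ValueError):
            binomial_tail(5, 6, 0.5)
        with pytest.raises(ValueError):
            binomial_tail(0, 0, 0.5)
        with pytest.raises(ValueError):
            binomial_tail(5, 2, 0.0)


class TestBDRank:
    def balanced_counts(self):
        # class totals equal -> q = 0.5 for both classes
        y = np.array([0, 0, 1, 1])
        counts = np.array(
            [
                # f0: 9 of 10 in class 1;  f1: 9 of 10 in class 0;  f2 absent
                [1, 4, 0],
                [0, 5, 0],
                [5, 1, 0],
                [4, 0, 0],
            ],
            dtype=float,
        )
        return counts, y

    def test_confidence_levels_and_order(self):
        counts, y = self.balanced_counts()
        ranked = bd_rank(counts, y)
        assert ranked.scores[0] == pytest.approx(1 - 11 / 1024)
        assert ranked.scores[1] == pytest.approx(1 - 11 / 1024)
        assert ranked.scores[2] == 0.0
        assert list(ranked.order) == [0, 1, 2]  # tie by index, absent last

    def test_absent_feature_ranks_last(self):
        counts, y = self.balanced_counts()
        ranked = bd_rank(counts, y)
        assert ranked.order[-1] == 2

    def test_class_with_zero_occurrences_errors(self):
        y = np.array([0, 0, 1, 1])
        counts = np.array([[1, 0], [2, 0], [0, 0], [0, 0]], dtype=float)
        with pytest.raises(ValueError):
            bd_rank(counts, y)

    def test_rejects_frequencies(self):
        y = np.array([0, 0, 1, 1])
        with pytest.raises(ValueError):
            bd_rank(np.array([[0.5, 0.5]] * 4), y)

    def test_cl_monotone_in_enrichment(self):
        """At fixed N, shifting occurrences toward one class cannot lower CL."""
        y = np.array([0, 0, 1, 1])
        prev = -1.0
        for n1 in range(5, 11):
            counts = np.zeros((4, 2))
            counts[2, 0] = n1          # feature 0: n1 of 10 in class 1
            counts[0, 0] = 10 - n1
            # balance feature holds both class totals at 60, so q stays 0.5
            counts[0, 1] = 50 + n1
            counts[2, 1] = 60 - n1
            cl = bd_rank(counts, y).scores[0]
            assert cl >= prev - 1e-12
            prev = cl


class TestIncrementalSubsetEval:
    def test_label_feature_first_gives_unit_accuracy_at_k1(self):
        rng = np.random.default_rng(4)
        y = np.array([0, 1] * 20)
        X = np.column_stack([y.astype(float), rng.random(40), rng.random(40)])
        ranking = mrmd_rank(X, y, "ED")
        assert ranking.order[0] == 0
        curve = incremental_subset_eval(X, y, ranking, k_max=3, folds=5, seed=0)
        assert curve.evaluations[0].accuracy == pytest.approx(1.0)
        assert curve.best_accuracy == pytest.approx(1.0)

    def test_deterministic_given_seed(self, separable_xy):
        X, y = separable_xy
        ranking = mrmd_rank(X, y, "ED")
        a = incremental_subset_eval(X, y, ranking, k_max=2, folds=5, seed=3)
        b = incremental_subset_eval(X, y, ranking, k_max=2, folds=5, seed=3)
        assert [e.accuracy for e in a.evaluations] == [e.accuracy for e in b.evaluations]

    def test_parsimony_selection_with_tolerance(self):
        rng = np.random.default_rng(9)
        y = np.array([0, 1] * 25)
        X = np.column_stack([y + rng.normal(0, 0.1, 50), rng.random(50)])
        ranking = mrmd_rank(X, y, "ED")
        curve = incremental_subset_eval(X, y, ranking, k_max=2, folds=5, seed=0,
                                        tolerance=1.0)
        assert curve.selected_k == 1  # everything is within tolerance 1.0

    def test_invalid_args(self, separable_xy):
        X, y = separable_xy
        ranking = mrmd_rank(X, y, "ED")
        with pytest.raises(ValueError):
            incremental_subset_eval(X, y, ranking, k_max=0)
        with pytest.raises(ValueError):
            incremental_subset_eval(X, y, ranking, k_max=2, folds=1)


class TestSelectors:
    def test_mrmd_selector_transform(self, separable_xy):
        X, y = separable_xy
        sel = MRMDSelector(k=1).fit(X, y)
        assert sel.transform(X).shape == (X.shape[0], 1)
        assert sel.get_support().sum() == 1
        # informative axis 0 must be the survivor
        assert sel.selected_indices_[0] == 0

    def test_binomial_selector_on_counts(self):
        rng = np.random.default_rng(2)
        y = np.repeat([0, 1], 10)
        counts = rng.poisson(2.0, size=(20, 6)).astype(float)
        counts[y == 1, 0] += 8  # enrich feature 0 in class 1
        sel = BinomialSelector(k=2).fit(counts, y)
        assert 0 in sel.selected_indices_
        assert sel.transform(counts).shape == (20, 2)

    def test_selector_k_bounds(self, separable_xy):
        X, y = separable_xy
        with pytest.raises(ValueError):
            MRMDSelector(k=3).fit(X, y)
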