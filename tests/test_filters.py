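"""Filter scorers and the budget-constrained top-down walk."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from costselect.data import CostModel, Dataset, default_feature_ids, within_budget
from costselect.filters import (
    DEFAULT_THRESHOLDS,
    ImportanceRanking,
    filter_select_topdown,
    score_adapter,
    score_symmetric_uncertainty,
    score_ttest,
)

from conftest import make_cost_model


class TestScoreTtest:
    def test_null_pvalues_are_uniform(self, rng):
        # 1000 pure-noise features: KS test against U(0,1) not rejected at 1%
        y = np.r_[np.zeros(100, dtype=int), np.ones(100, dtype=int)]
        X = rng.standard_normal((200, 1000))
        d = Dataset(X, y, default_feature_ids(1000))
        ranking = score_ttest(d)
        ks = stats.kstest(ranking.scores, "uniform")
        assert ks.pvalue > 0.01

    def test_strong_effect_detected(self, rng):
        y = (rng.random(500) < 0.5).astype(int)
        X = rng.standard_normal((500, 2))
        X[:, 0] += y  # group means 0 vs 1, sd 1
        d = Dataset(X, y, default_feature_ids(2))
        ranking = score_ttest(d)
        assert ranking.scores[0] < 1e-10
        assert ranking.direction == "lower"

    def test_affine_rescaling_invariance(self, rng):
        y = (rng.random(200) < 0.5).astype(int)
        x = rng.standard_normal(200) + 0.3 * y
        d1 = Dataset(x[:, None], y, ("X1",))
        d2 = Dataset((7.0 * x + 3.0)[:, None], y, ("X1",))
        p1 = score_ttest(d1).scores[0]
        p2 = score_ttest(d2).scores[0]
        assert p1 == pytest.approx(p2, rel=1e-9)

    def test_degenerate_feature_flagged_missing_and_ranked_last(self, rng):
        y = np.r_[np.zeros(50, dtype=int), np.ones(50, dtype=int)]
        X = np.column_stack([rng.standard_normal(100) + y, np.full(100, 3.0)])
        d = Dataset(X, y, ("good", "constant"))
        ranking = score_ttest(d)
        assert np.isnan(ranking.scores[1])
        assert ranking.rank_order()[-1] == 1


class TestScoreSymmetricUncertainty:
    def test_deterministic_copy_of_response_scores_one(self):
        y = np.tile([0, 1], 200)
        x = y.astype(float) * 2 - 1  # bin-wise copy of y
        d = Dataset(x[:, None], y, ("X1",))
        su = score_symmetric_uncertainty(d, bins=2).scores[0]
        assert su == pytest.approx(1.0, abs=1e-9)

    def test_independent_feature_scores_near_zero(self, rng):
        y = (rng.random(5000) < 0.5).astype(int)
        d = Dataset(rng.standard_normal((5000, 1)), y, ("X1",))
        su = score_symmetric_uncertainty(d).scores[0]
        assert su < 0.01

    def test_degenerate_feature_scores_zero(self, rng):
        y = (rng.random(100) < 0.5).astype(int)
        d = Dataset(np.full((100, 1), 2.0), y, ("X1",))
        assert score_symmetric_uncertainty(d).scores[0] == 0.0

    def test_symmetry_in_arguments(self, rng):
        # SU(X;Y) = SU(Y;X) when X is already binary-coded like Y
        y = (rng.random(400) < 0.5).astype(int)
        x = ((rng.random(400) < 0.3) ^ (y == 1)).astype(int)
        d_xy = Dataset(x[:, None].astype(float), y, ("X1",))
        d_yx = Dataset(y[:, None].astype(float), x, ("X1",))
        su_xy = score_symmetric_uncertainty(d_xy, bins=2).scores[0]
        su_yx = score_symmetric_uncertainty(d_yx, bins=2).scores[0]
        assert su_xy == pytest.approx(su_yx, abs=1e-9)


class TestScoreAdapter:
    def test_negated_pvalues_reproduce_ttest_selection(self, rng):
        y = (rng.random(300) < 0.5).astype(int)
        X = rng.standard_normal((300, 6))
        X[:, 2] += 0.8 * y
        d = Dataset(X, y, default_feature_ids(6))
        model = make_cost_model([0.2] * 6, budget=0.6)
        direct = filter_select_topdown(score_ttest(d), model, threshold=None)

        def neg_p(features, response):
            return -score_ttest(Dataset(features, response,
                                        default_feature_ids(features.shape[1]))).scores

        wrapped = score_adapter(d, neg_p, method_label="neg-ttest", direction="higher")
        via_adapter = filter_select_topdown(wrapped, model, threshold=None)
        assert direct.members == via_adapter.members

    def test_constant_scorer_ties_resolved_by_index(self, rng):
        y = (rng.random(50) < 0.5).astype(int)
        d = Dataset(rng.standard_normal((50, 4)), y, default_feature_ids(4))
        ranking = score_adapter(d, lambda X, y: np.ones(4))
        np.testing.assert_array_equal(ranking.rank_order(), [0, 1, 2, 3])

    def test_non_finite_score_rejected_with_id(self, rng):
        y = (rng.random(50) < 0.5).astype(int)
        d = Dataset(rng.standard_normal((50, 3)), y, default_feature_ids(3))
        with pytest.raises(ValueError, match="X2"):
            score_adapter(d, lambda X, y: np.array([1.0, np.inf, 2.0]))

    def test_length_mismatch_rejected(self, rng):
        y = (rng.random(50) < 0.5).astype(int)
        d = Dataset(rng.standard_normal((50, 3)), y, default_feature_ids(3))
        with pytest.raises(ValueError, match="3 features"):
            score_adapter(d, lambda X, y: np.ones(2))


class TestTopDownSelection:
    def _ranking(self, scores, ids, direction="higher"):
        return ImportanceRanking(np.asarray(scores, float), direction, "custom", ids)

    def test_zero_budget_gives_empty_set(self):
        model = make_cost_model([0.5, 0.5], budget=0.0)
        r = self._ranking([2, 1], ("X1", "X2"))
        assert filter_select_topdown(r, model).members == ()

    def test_hand_walk_unaffordable_features_skipped(self):
        # ranks A > B > C, costs 0.9/0.5/0.5, budget 1.0: A in, B and C
        # unaffordable on the remaining 0.1 -> {A}
        model = CostModel(pd.Series({"A": 0.9, "B": 0.5, "C": 0.5}), budget=1.0)
        r = self._ranking([3, 2, 1], ("A", "B", "C"))
        assert filter_select_topdown(r, model).members == ("A",)

    def test_skipped_feature_does_not_block_later_affordable_one(self):
        model = CostModel(pd.Series({"A": 0.9, "B": 0.5, "C": 0.1}), budget=1.0)
        r = self._ranking([3, 2, 1], ("A", "B", "C"))
        assert filter_select_topdown(r, model).members == ("A", "C")
        strict = filter_select_topdown(r, model, stop_at_first_unaffordable=True)
        assert strict.members == ("A",)

    def test_equal_costs_no_threshold_selects_top_k(self, rng):
        scores = rng.random(10)
        model = make_cost_model([0.2] * 10, budget=0.65)  # k = floor(0.65/0.2) = 3
        r = self._ranking(scores, default_feature_ids(10))
        selected = filter_select_topdown(r, model).members
        top3 = [default_feature_ids(10)[j] for j in np.argsort(-scores)[:3]]
        assert list(selected) == top3

    def test_threshold_stops_the_walk(self):
        model = CostModel(pd.Series({"A": 0.1, "B": 0.1, "C": 0.1}), budget=1.0)
        r = self._ranking([0.01, 0.04, 0.2], ("A", "B", "C"), direction="lower")
        res = filter_select_topdown(r, model, threshold=0.05)
        assert res.members == ("A", "B")

    def test_default_thresholds_wired_to_shipped_scorers(self, rng):
        assert DEFAULT_THRESHOLDS == {"ttest": 0.05, "symmetric_uncertainty": 1e-6}
        y = (rng.random(200) < 0.5).astype(int)
        X = rng.standard_normal((200, 5))
        X[:, 0] += 1.5 * y
        d = Dataset(X, y, default_feature_ids(5))
        model = make_cost_model([0.1] * 5, budget=0.5)
        res = filter_select_topdown(score_ttest(d), model)
        # only the separating feature passes p <= 0.05 with high probability
        assert "X1" in res.members
        assert res.extra["threshold"] == 0.05

    def test_selection_always_within_budget(self, rng):
        y = (rng.random(100) < 0.5).astype(int)
        d = Dataset(rng.standard_normal((100, 20)), y, default_feature_ids(20))
        ranking = score_ttest(d)
        for _ in range(50):
            costs = rng.uniform(0.1, 1, 20)
            budget = rng.uniform(0, costs.sum())
            model = make_cost_model(costs, budget=budget)
            res = filter_select_topdown(ranking, model, threshold=None)
            assert within_budget(res.members, model)
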