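"""Genetic selectors: fitness contracts, operator closure, and convergence."""

import numpy as np
import pandas as pd
import pytest
from costselect.data import CostModel, FeatureSet, default_feature_ids, within_budget
from costselect.genetic import (
    GAConfig,
    cc_crossover,
    cc_mutate,
    fga_fitness,
    init_individual_cga,
    init_population_fga,
    rank_selection_indices,
    run_ga,
    uniform_crossover,
)
from conftest import make_cost_model


def _fset(cost):
    return FeatureSet(members=frozenset({"X1"}), total_cost=cost)


class TestFgaFitness:
    def test_double_budget_gives_minus_one(self):
        model = make_cost_model([1.0], budget=2.0)
        assert fga_fitness(_fset(4.0), None, model) == pytest.approx(-1.0)

    def test_feasible_is_reciprocal_aic(self):
        model = make_cost_model([1.0], budget=2.0)
        aic = 2 - 2 * 500 * np.log(0.5)  # intercept-only value at n=500
        assert fga_fitness(_fset(1.0), aic, model) == pytest.approx(0.0014387, abs=1e-6)

    def test_sign_separates_feasibility(self):
        model = make_cost_model([1.0], budget=2.0)
        just_over = fga_fitness(_fset(2.0 + 1e-6), None, model)
        assert just_over < 0
        assert fga_fitness(_fset(2.0), 100.0, model) > just_over

    def test_negative_aic_inside_budget_is_an_error(self):
        model = make_cost_model([1.0], budget=2.0)
        with pytest.raises(ValueError, match="reserved-sign"):
            fga_fitness(_fset(1.0), -5.0, model)


class TestInitPopulationFga:
    def test_budget_covers_everything_includes_all(self, rng):
        model = make_cost_model([0.5] * 20, budget=100.0)
        pop = init_population_fga(model, 50, rng)
        assert pop.all()

    def test_expected_cost_equals_budget(self, rng):
        # unit costs, p=500, c_max=10: expected individual cost is 10
        model = make_cost_model([1.0] * 500, budget=10.0)
        pop = init_population_fga(model, 4000, rng)
        mean_cost = pop.sum(axis=1).mean()
        se = np.sqrt(10 * (1 - 10 / 500) / 4000)
        assert abs(mean_cost - 10.0) < 4 * se


class TestInitIndividualCga:
    def test_pstop_one_returns_empty(self, rng):
        costs = np.full(10, 0.5)
        bits = init_individual_cga(costs, 2.0, p_stop=1.0, rng=rng)
        assert not bits.any()

    def test_budget_below_minimum_cost_gives_empty(self, rng):
        costs = np.full(10, 0.5)
        bits = init_individual_cga(costs, 0.2, p_stop=1e-9, rng=rng)
        assert not bits.any()

    def test_always_within_budget(self, rng):
        costs = rng.uniform(0.1, 1, 30)
        for _ in range(2000):
            budget = rng.uniform(0, costs.sum())
            bits = init_individual_cga(costs, budget, p_stop=1 / 500, rng=rng)
            assert costs[bits].sum() <= budget + 1e-9


class TestCcCrossover:
    def test_identical_parents_reproduce(self, rng):
        costs = np.full(10, 0.3)
        a = np.zeros(10, dtype=bool)
        a[:5] = True
        ca, cb = cc_crossover(a, a, costs, budget=2.0, rng=rng)
        assert (ca == a).all() and (cb == a).all()

    def test_empty_parent_splits_the_other(self, rng):
        costs = np.full(10, 0.3)
        a = np.zeros(10, dtype=bool)
        b = np.zeros(10, dtype=bool)
        b[:6] = True
        ca, cb = cc_crossover(a, b, costs, budget=3.0, rng=rng)
        union = ca | cb
        assert not (union & ~b).any()  # children only draw from b
        assert costs[ca].sum() <= 3.0 + 1e-9 and costs[cb].sum() <= 3.0 + 1e-9

    def test_disjoint_budget_filling_parents_stay_feasible(self, rng):
        costs = np.ones(20)
        a = np.zeros(20, dtype=bool)
        b = np.zeros(20, dtype=bool)
        a[:10] = True
        b[10:] = True
        for _ in range(3000):
            ca, cb = cc_crossover(a, b, costs, budget=10.0, rng=rng)
            assert ca.sum() <= 10 and cb.sum() <= 10

    def test_infeasible_parent_rejected(self, rng):
        costs = np.ones(5)
        a = np.ones(5, dtype=bool)
        with pytest.raises(ValueError, match="feasible"):
            cc_crossover(a, a, costs, budget=3.0, rng=rng)


class TestCcMutate:
    def test_empty_set_always_adds(self, rng):
        costs = np.full(10, 0.3)
        bits = np.zeros(10, dtype=bool)
        for _ in range(200):
            out = cc_mutate(bits, costs, budget=1.0, rng=rng)
            assert out.sum() == 1

    def test_full_budget_always_removes(self, rng):
        costs = np.ones(10)
        bits = np.zeros(10, dtype=bool)
        bits[:4] = True
        for _ in range(200):
            out = cc_mutate(bits, costs, budget=4.0, rng=rng)
            assert out.sum() == 3

    def test_half_budget_add_probability(self, rng):
        # cost(s) = c_max/2 -> P(add) = 0.5, checked by frequency
        costs = np.ones(100)
        bits = np.zeros(100, dtype=bool)
        bits[:5] = True
        n = 100_000
        adds = 0
        for _ in range(n):
            out = cc_mutate(bits, costs, budget=10.0, rng=rng)
            adds += out.sum() > 5
        se = np.sqrt(0.25 / n)
        assert abs(adds / n - 0.5) < 3 * se

    def test_add_decided_but_nothing_fits_removes_instead(self, rng):
        costs = np.array([0.4, 0.4, 5.0])
        bits = np.array([True, False, False])
        # budget 0.5: remaining 0.1 fits nothing, yet P(add) = 1 - 0.4/0.5 = 0.2
        seen_sizes = set()
        for _ in range(500):
            out = cc_mutate(bits, costs, budget=0.5, rng=rng)
            seen_sizes.add(int(out.sum()))
            assert costs[out].sum() <= 0.5 + 1e-9
        assert seen_sizes == {0}  # every path ends in a removal

    def test_empty_set_with_nothing_affordable_is_unchanged(self, rng):
        costs = np.array([5.0, 5.0])
        bits = np.zeros(2, dtype=bool)
        out = cc_mutate(bits, costs, budget=1.0, rng=rng)
        assert not out.any()


class TestRankSelection:
    def test_single_individual_always_selected(self, rng):
        idx = rank_selection_indices(np.array([3.0]), 10, rng)
        assert (idx == 0).all()

    def test_two_individuals_best_wins_two_thirds(self, rng):
        fits = np.array([1.0, 2.0])
        idx = rank_selection_indices(fits, 60_000, rng)
        frac_best = (idx == 1).mean()
        se = np.sqrt(2 / 9 / 60_000)
        assert abs(frac_best - 2 / 3) < 3 * se

    def test_permutation_invariance_of_selection_distribution(self, rng):
        fits = np.array([5.0, 1.0, 3.0])
        idx = rank_selection_indices(fits, 90_000, rng)
        fracs = np.bincount(idx, minlength=3) / idx.size
        np.testing.assert_allclose(fracs, [3 / 6, 1 / 6, 2 / 6], atol=0.01)


class TestRunGa:
    @pytest.fixture
    def small_cfg(self):
        return dict(population_size=30, max_iterations=40, convergence_patience=8)

    def test_cga_every_individual_feasible(self, toy_problem, small_cfg):
        cfg = GAConfig(variant="cga", seed=1, **small_cfg)
        res = run_ga(toy_problem.train, toy_problem.cost_model, cfg)
        assert res.feasible
        assert within_budget(res.members, toy_problem.cost_model)

    def test_fixed_seed_is_deterministic(self, toy_problem, small_cfg):
        cfg = GAConfig(variant="cga", seed=9, **small_cfg)
        r1 = run_ga(toy_problem.train, toy_problem.cost_model, cfg)
        r2 = run_ga(toy_problem.train, toy_problem.cost_model, cfg)
        assert r1.members == r2.members
        assert r1.trace == r2.trace

    def test_best_so_far_fitness_nondecreasing(self, toy_problem, small_cfg):
        for variant in ("cga", "fga"):
            cfg = GAConfig(variant=variant, seed=2, **small_cfg)
            res = run_ga(toy_problem.train, toy_problem.cost_model, cfg)
            running = np.maximum.accumulate(res.trace)
            # with 1-elitism the per-generation best never falls below the
            # best-so-far of earlier generations
            assert np.all(np.asarray(res.trace) >= running - 1e-12)

    def test_fga_no_feasible_solution_is_explicit(self, small_cfg):
        # only the empty set is feasible (every cost exceeds the budget) and
        # with p=30 coin-flip features and no mutation a short run never
        # reaches it, so the result must say so explicitly
        gen = np.random.default_rng(0)
        from costselect.data import Dataset

        p = 30
        d = Dataset(gen.standard_normal((60, p)), (gen.random(60) < 0.5).astype(int),
                    default_feature_ids(p))
        model = CostModel(pd.Series([5.0] * p, index=d.feature_ids), budget=1.0)
        cfg = GAConfig(variant="fga", init="uniform", seed=3,
                       population_size=10, max_iterations=3,
                       convergence_patience=2, mutation_rate=0.0)
        res = run_ga(d, model, cfg)
        assert not res.feasible
        assert res.members == ()
        assert res.score is None

    def test_uniform_crossover_children_union_of_parents(self, rng):
        a = np.zeros(12, dtype=bool)
        b = np.zeros(12, dtype=bool)
        a[:6] = True
        b[4:8] = True
        ca, cb = uniform_crossover(a, b, rng)
        shared = a & b
        assert (ca & shared).sum() == shared.sum()
        assert not (ca & ~(a | b)).any()
        assert not (cb & ~(a | b)).any()
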