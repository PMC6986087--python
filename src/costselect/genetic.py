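"""Genetic-algorithm selectors under a hard feature-cost budget.

Two adaptation strategies are implemented on top of a common
generational loop (linear-rank survivor selection, crossover, mutation,
1-elitism):

``fGA`` — fitness adaptation.  Standard cost-agnostic operators (uniform
crossover, random toggle mutation) are kept, and infeasibility is handled
in the fitness itself:

    fitness(s) = 1 - costs(s)/c_max   if costs(s) > c_max   (negative, graded)
               = 1 / AIC(s)           otherwise              (positive)

The graded negative branch lets the population evolve from large
violations towards the feasible region instead of wandering blindly, and
the sign of the fitness encodes feasibility exactly (assuming AIC > 0;
a negative AIC inside the budget breaks the reserved-sign contract and
raises).  Infeasible candidates never cost a model fit.

``cGA`` — cost-preserving operators.  Initialization (random forward
selection with a per-step stop probability), crossover, and mutation are
all constructed so that every individual ever evaluated satisfies the
budget; the fitness is then simply the negative AIC and needs no
constraint handling.

Individuals are bit-vectors over the fixed feature universe.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .data import BUDGET_TOL, CostModel, Dataset, FeatureSet, SelectionResult
from .scoring import SubsetScorer

__all__ = [
    "GAConfig",
    "Population",
    "fga_fitness",
    "init_population_fga",
    "init_individual_cga",
    "uniform_crossover",
    "random_toggle_mutation",
    "cc_crossover",
    "cc_mutate",
    "rank_selection_indices",
    "run_ga",
]


@dataclass(frozen=True)
class GAConfig:
    """Genetic-algorithm hyperparameters.

    Defaults follow the simulation configuration used throughout this
    package: population 500, at most 150 generations, convergence after 10
    consecutive generations without best-fitness improvement, and a
    per-step stop probability of 1/500 for the random forward
    initialization of the cost-preserving variant (small pStop favours
    large, budget-filling start sets).

    ``init`` selects the fGA start population: ``"cost_scaled"`` includes
    each feature with probability min(1, c_max / sum(c)) so the average
    start cost equals the budget; ``"uniform"`` is the classical coin-flip
    initialization, which in tightly constrained problems starts deep in
    the infeasible region.  cGA always uses the random forward
    initialization.
    """

    variant: str = "cga"
    population_size: int = 500
    max_iterations: int = 150
    convergence_patience: int = 10
    p_stop: float = 1.0 / 500.0
    crossover_rate: float = 0.8
    mutation_rate: float = 0.1
    init: str = "cost_scaled"
    elitism: bool = True
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        v = self.variant.lower()
        if v not in ("fga", "cga"):
            raise ValueError(f"variant must be 'fga' or 'cga', got {self.variant!r}")
        if self.population_size < 2:
            raise ValueError("population_size must be at least 2")
        if self.convergence_patience < 1:
            raise ValueError("convergence_patience must be at least 1")
        if not (0.0 < self.p_stop <= 1.0):
            raise ValueError("p_stop must lie in (0, 1]")
        if self.init not in ("cost_scaled", "uniform"):
            raise ValueError("init must be 'cost_scaled' or 'uniform'")
        object.__setattr__(self, "variant", v)


@dataclass
class Population:
    """Bit-matrix of individuals with their fitness values."""

    individuals: np.ndarray  # (m, p) bool
    fitnesses: np.ndarray  # (m,) float
    generation: int = 0


# ---------------------------------------------------------------------------
# fitness
# ---------------------------------------------------------------------------


def fga_fitness(fset: FeatureSet, aic: Optional[float], model: CostModel) -> float:
    """Graded constraint-violation fitness.

    Negative values are reserved for budget violations (``1 - cost/c_max``,
    more negative for larger violations); feasible sets score the
    reciprocal AIC.  ``aic`` may be None for infeasible sets (it is not
    needed there).
    """
    if model.budget <= 0:
        raise ValueError("fGA fitness requires a positive budget")
    if fset.total_cost > model.budget + BUDGET_TOL:
        return 1.0 - fset.total_cost / model.budget
    if aic is None:
        raise ValueError("feasible set requires its AIC")
    if aic <= 0:
        raise ValueError(
            "non-positive AIC inside the budget breaks the reserved-sign "
            "fitness contract (negative values encode violations)"
        )
    return 1.0 / aic


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------


def init_population_fga(
    model: CostModel, size: int, rng: np.random.Generator, mode: str = "cost_scaled"
) -> np.ndarray:
    """Random start population for the fitness-adapted GA.

    ``cost_scaled``: each feature enters independently with probability
    min(1, c_max / sum(c)), so an individual's expected total cost equals
    min(c_max, sum(c)).  ``uniform``: probability 1/2 per feature.
    """
    p = len(model.feature_ids)
    if mode == "cost_scaled":
        prob = min(1.0, model.budget / float(model.costs.sum()))
    elif mode == "uniform":
        prob = 0.5
    else:
        raise ValueError(f"unknown init mode {mode!r}")
    return rng.random((size, p)) < prob


def init_individual_cga(
    costs: np.ndarray, budget: float, p_stop: float, rng: np.random.Generator
) -> np.ndarray:
    """Random forward selection: a budget-feasible start individual.

    Starting from the empty set, each step first returns the current set
    with probability ``p_stop``, then draws a uniformly random not-yet-tried
    feature and adds it if it fits the remaining budget; the first
    unaffordable draw terminates.  Every returned set is feasible by
    construction.
    """
    p = costs.size
    bits = np.zeros(p, dtype=bool)
    remaining = budget
    order = rng.permutation(p)
    for j in order:
        if rng.random() < p_stop:
            return bits
        if costs[j] <= remaining + BUDGET_TOL:
            bits[j] = True
            remaining -= costs[j]
        else:
            return bits
    return bits


# ---------------------------------------------------------------------------
# cost-agnostic operators (fGA)
# ---------------------------------------------------------------------------


def uniform_crossover(
    a: np.ndarray, b: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Classical uniform crossover: shared features pass to both children,
    each single-parent feature is carried to each child by a fair coin."""
    shared = a & b
    diff = np.flatnonzero(a ^ b)
    ca = shared.copy()
    cb = shared.copy()
    ca[diff] = rng.random(diff.size) < 0.5
    cb[diff] = rng.random(diff.size) < 0.5
    return ca, cb


def random_toggle_mutation(bits: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Toggle one uniformly random feature of the whole pool (add if absent,
    remove if present)."""
    out = bits.copy()
    j = rng.integers(bits.size)
    out[j] = ~out[j]
    return out


# ---------------------------------------------------------------------------
# cost-preserving operators (cGA)
# ---------------------------------------------------------------------------


def cc_crossover(
    a: np.ndarray,
    b: np.ndarray,
    costs: np.ndarray,
    budget: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Cost-constrained crossover.

    Features present in both parents are forwarded to both children.
    Features present in exactly one parent are visited in random order; a
    fair coin assigns each to one child, and it is added only if that
    child's remaining budget allows it.  Both children are feasible
    whenever both parents are.
    """
    cost_a = float(costs[a].sum())
    cost_b = float(costs[b].sum())
    if cost_a > budget + BUDGET_TOL or cost_b > budget + BUDGET_TOL:
        raise ValueError("cc_crossover requires budget-feasible parents")
    shared = a & b
    ca = shared.copy()
    cb = shared.copy()
    base = float(costs[shared].sum())
    rem_a = budget - base
    rem_b = budget - base
    diff = np.flatnonzero(a ^ b)
    for j in rng.permutation(diff):
        c = costs[j]
        if c > rem_a + BUDGET_TOL and c > rem_b + BUDGET_TOL:
            continue
        if rng.random() < 0.5:
            if c <= rem_a + BUDGET_TOL:
                ca[j] = True
                rem_a -= c
        else:
            if c <= rem_b + BUDGET_TOL:
                cb[j] = True
                rem_b -= c
    return ca, cb


def cc_mutate(
    bits: np.ndarray,
    costs: np.ndarray,
    budget: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Cost-constrained mutation.

    The add/remove decision is made in advance with

        P(add) = 1 - costs(s) / c_max,

    so near-empty sets almost always grow while budget-filling sets shrink
    to explore elsewhere.  An "add" decision picks uniformly among absent
    features that fit the remaining budget; if none fits, a random member
    is removed instead.  A "remove" decision drops a uniformly random
    member (an empty set is returned unchanged).  Feasibility is preserved.
    """
    cost = float(costs[bits].sum())
    if cost > budget + BUDGET_TOL:
        raise ValueError("cc_mutate requires a budget-feasible input set")
    out = bits.copy()
    p_add = 1.0 - cost / budget if budget > 0 else 0.0
    if rng.random() < p_add:
        remaining = budget - cost
        addable = np.flatnonzero(~bits & (costs <= remaining + BUDGET_TOL))
        if addable.size:
            out[rng.choice(addable)] = True
            return out
        # add decided but nothing fits: fall through to removal
    members = np.flatnonzero(out)
    if members.size:
        out[rng.choice(members)] = False
    return out


# ---------------------------------------------------------------------------
# selection
# ---------------------------------------------------------------------------


def rank_selection_indices(
    fitnesses: np.ndarray, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Linear-rank survivor sampling (with replacement).

    The worst individual gets weight 1, the best weight m, normalized by
    m(m+1)/2; only fitness ranks matter, not magnitudes, so the selection
    distribution is invariant to order permutations and monotone fitness
    transforms.
    """
    m = fitnesses.size
    if m == 0:
        raise ValueError("empty population")
    order = np.argsort(fitnesses, kind="stable")  # worst .. best
    ranks = np.empty(m)
    ranks[order] = np.arange(1, m + 1)
    probs = ranks / (m * (m + 1) / 2.0)
    return rng.choice(m, size=size, replace=True, p=probs)


# ---------------------------------------------------------------------------
# main loop
# ---------------------------------------------------------------------------


def _evaluate(
    pop_bits: np.ndarray,
    ids: tuple[str, ...],
    costs: np.ndarray,
    model: CostModel,
    scorer: SubsetScorer,
    variant: str,
) -> np.ndarray:
    """Fitness of every individual; fGA skips model fits for infeasible sets."""
    m = pop_bits.shape[0]
    fits = np.empty(m)
    id_arr = np.asarray(ids, dtype=object)
    for i in range(m):
        bits = pop_bits[i]
        cost = float(costs[bits].sum())
        members = frozenset(id_arr[bits])
        if variant == "fga":
            fset = FeatureSet(members=members, total_cost=cost)
            if cost > model.budget + BUDGET_TOL:
                fits[i] = fga_fitness(fset, None, model)
            else:
                fits[i] = fga_fitness(fset, scorer.aic(members), model)
        else:
            if cost > model.budget + BUDGET_TOL:
                raise AssertionError(
                    "cGA invariant broken: infeasible individual reached evaluation"
                )
            fits[i] = -scorer.aic(members)
    return fits


def run_ga(
    data: Dataset,
    model: CostModel,
    cfg: GAConfig,
    rng: Optional[np.random.Generator] = None,
    scorer: Optional[SubsetScorer] = None,
) -> SelectionResult:
    """Run the configured genetic algorithm and return the best feasible set.

    The loop is: fitness evaluation, linear-rank selection, crossover
    (on a fraction of the selected pairs), mutation (on a fraction of
    individuals), 1-elitism (the best individual so far replaces one slot
    unchanged).  Termination after ``max_iterations`` generations or
    ``convergence_patience`` consecutive generations without best-fitness
    improvement (absolute tolerance 1e-12).

    For fGA the best *feasible* individual ever evaluated is returned; if
    none was found the result carries ``feasible=False`` and an empty
    member list.  For cGA every evaluated individual is feasible by
    construction.
    """
    if model.budget <= 0 and cfg.variant == "fga":
        raise ValueError("fGA requires a positive budget")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if scorer is None:
        scorer = SubsetScorer(data)
    ids = data.feature_ids
    costs = model.cost_vector(ids)
    m = cfg.population_size
    p = len(ids)

    if cfg.variant == "fga":
        pop = init_population_fga(model, m, rng, mode=cfg.init)
    else:
        pop = np.stack(
            [init_individual_cga(costs, model.budget, cfg.p_stop, rng) for _ in range(m)]
        )

    fits = _evaluate(pop, ids, costs, model, scorer, cfg.variant)
    best_idx = int(np.argmax(fits))
    best_fitness = float(fits[best_idx])
    best_bits = pop[best_idx].copy()
    # best feasible ever (for fGA the sign of the fitness encodes feasibility)
    best_feas_bits = None
    best_feas_fitness = -np.inf
    trace = [best_fitness]
    mean_trace = [float(fits.mean())]

    def note_feasible(bits_mat: np.ndarray, fit_vec: np.ndarray) -> None:
        nonlocal best_feas_bits, best_feas_fitness
        feas = bits_mat @ costs <= model.budget + BUDGET_TOL
        if feas.any():
            sub = np.flatnonzero(feas)
            k = sub[int(np.argmax(fit_vec[sub]))]
            if fit_vec[k] > best_feas_fitness:
                best_feas_fitness = float(fit_vec[k])
                best_feas_bits = bits_mat[k].copy()

    note_feasible(pop, fits)

    stall = 0
    generations = 0
    tol = 1e-12
    for gen in range(1, cfg.max_iterations + 1):
        survivors = pop[rank_selection_indices(fits, m, rng)]
        # crossover on consecutive pairs
        nxt = survivors.copy()
        for i in range(0, m - 1, 2):
            if rng.random() < cfg.crossover_rate:
                if cfg.variant == "cga":
                    ca, cb = cc_crossover(nxt[i], nxt[i + 1], costs, model.budget, rng)
                else:
                    ca, cb = uniform_crossover(nxt[i], nxt[i + 1], rng)
                nxt[i], nxt[i + 1] = ca, cb
        # mutation
        for i in range(m):
            if rng.random() < cfg.mutation_rate:
                if cfg.variant == "cga":
                    nxt[i] = cc_mutate(nxt[i], costs, model.budget, rng)
                else:
                    nxt[i] = random_toggle_mutation(nxt[i], rng)
        if cfg.elitism:
            nxt[0] = best_bits
        pop = nxt
        fits = _evaluate(pop, ids, costs, model, scorer, cfg.variant)
        note_feasible(pop, fits)
        gen_best = int(np.argmax(fits))
        generations = gen
        if fits[gen_best] > best_fitness + tol:
            best_fitness = float(fits[gen_best])
            best_bits = pop[gen_best].copy()
            stall = 0
        else:
            stall += 1
        trace.append(float(fits.max()))
        mean_trace.append(float(fits.mean()))
        if stall >= cfg.convergence_patience:
            break

    if best_feas_bits is None:
        return SelectionResult(
            method=cfg.variant,
            members=(),
            total_cost=0.0,
            score=None,
            trace=trace,
            n_evaluations=scorer.n_evaluations,
            seed=cfg.seed,
            feasible=False,
            converged=stall >= cfg.convergence_patience,
            extra={"generations": generations, "mean_fitness": mean_trace},
        )

    members = tuple(ids[j] for j in np.flatnonzero(best_feas_bits))
    final = scorer.fit(members)
    return SelectionResult(
        method=cfg.variant,
        members=members,
        total_cost=float(costs[best_feas_bits].sum()),
        score=final.aic,
        trace=trace,
        n_evaluations=scorer.n_evaluations,
        seed=cfg.seed,
        feasible=True,
        converged=stall >= cfg.convergence_patience,
        extra={"generations": generations, "mean_fitness": mean_trace},
    )
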