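"""Evaluation harness: feature-recovery metrics, reference baselines, and
the multi-setting benchmark runner.

Feature recovery is summarized from the 2x2 contingency of relevance
(ground truth) against selection: precision is the fraction of selected
features that are truly relevant, recall the fraction of relevant features
that were selected.  Two analytic references put these numbers in context:

* random selection has expected precision p_rel / p regardless of the
  subset size (hypergeometric expectation), and expected recall
  c_max / (mean cost * p) once the typical affordable model size
  c_max / mean(c) is plugged in;
* the budget itself caps the recall at gamma in settings with gamma <= 1,
  since at most the cheapest gamma-fraction of the relevant cost fits.

The module also provides the two closed-form operator motivations for the
cost-preserving genetic operators: the budget-violation probability of an
unconstrained uniform crossover of budget-filling parents (a binomial
tail) and the add-probability of a cost-agnostic toggle mutation.
"""

from __future__ import annotations

import time
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data import SelectionResult
from .filters import (
    filter_select_topdown,
    score_symmetric_uncertainty,
    score_ttest,
)
from .genetic import GAConfig, run_ga
from .greedy import GreedyConfig, forward_select
from .scoring import SubsetScorer, evaluate_auc
from .simulate import SettingSpec, SimulatedProblem, realize_setting, replicate_rng

__all__ = [
    "RecoveryMetrics",
    "recovery_metrics",
    "random_precision",
    "random_recall",
    "crossover_violation_probability",
    "naive_mutation_add_probability",
    "run_method",
    "run_benchmark",
    "METHOD_LABELS",
]


@dataclass(frozen=True)
class RecoveryMetrics:
    """Precision/recall of feature recovery.

    Precision is None (missing) for an empty selection rather than 0 or 1;
    aggregations skip missing values.
    """

    precision: Optional[float]
    recall: float
    n_selected: int
    n_relevant_selected: int


def recovery_metrics(
    selected: Iterable[str], relevance_mask: np.ndarray, feature_ids: Sequence[str]
) -> RecoveryMetrics:
    """Contingency-based precision/recall of a selected set against the truth."""
    mask = np.asarray(relevance_mask, dtype=bool)
    if mask.size != len(feature_ids):
        raise ValueError("relevance mask must cover the feature universe")
    relevant = {fid for fid, rel in zip(feature_ids, mask) if rel}
    sel = set(selected)
    unknown = sel - set(feature_ids)
    if unknown:
        raise KeyError(f"selected feature {next(iter(unknown))!r} not in universe")
    n_sel = len(sel)
    n_hit = len(sel & relevant)
    p_rel = len(relevant)
    precision = n_hit / n_sel if n_sel > 0 else None
    recall = n_hit / p_rel if p_rel > 0 else 0.0
    return RecoveryMetrics(
        precision=precision,
        recall=recall,
        n_selected=n_sel,
        n_relevant_selected=n_hit,
    )


def random_precision(p: int, p_rel: int) -> float:
    """Expected precision of a uniformly random subset: p_rel / p.

    Independent of the subset size (hypergeometric expectation n p_rel / p
    divided by n).
    """
    if p < 1:
        raise ValueError("p must be at least 1")
    if not (0 <= p_rel <= p):
        raise ValueError("need 0 <= p_rel <= p")
    return p_rel / p


def random_recall(budget: float, mean_cost: float, p: int, p_rel: int) -> float:
    """Expected recall of a random subset of the typical affordable size.

    The budget admits on average c_max / mean(c) features; the expected
    number of relevant ones among a random subset of that size is
    hypergeometric, giving recall budget / (mean_cost * p), capped at 1.
    """
    if mean_cost <= 0:
        raise ValueError("mean cost must be positive")
    if budget < 0:
        raise ValueError("budget must be non-negative")
    if p_rel == 0:
        return 0.0
    return min(1.0, budget / (mean_cost * p))


def crossover_violation_probability(
    n_disjoint: int,
    unit_cost: float,
    budget: float,
    mode: str = "analytic",
    n_trials: int = 100_000,
    rng: Optional[np.random.Generator] = None,
) -> float:
    """Budget-violation probability of an unconstrained uniform crossover.

    Two disjoint parents with ``n_disjoint`` distinct unit-cost features in
    total; a child receives each by a fair coin, so its feature count is
    Binomial(n_disjoint, 1/2) and it violates the budget when the count
    exceeds floor(budget / unit_cost).  ``analytic`` evaluates the exact
    binomial upper tail; ``montecarlo`` simulates coin flips.
    """
    if n_disjoint < 0:
        raise ValueError("n_disjoint must be non-negative")
    if unit_cost <= 0:
        raise ValueError("unit_cost must be positive")
    limit = int(np.floor(budget / unit_cost + 1e-12))
    if limit >= n_disjoint:
        return 0.0
    if mode == "analytic":
        return float(stats.binom.sf(limit, n_disjoint, 0.5))
    if mode == "montecarlo":
        if rng is None:
            rng = np.random.default_rng()
        counts = rng.binomial(n_disjoint, 0.5, size=n_trials)
        return float(np.mean(counts > limit))
    raise ValueError("mode must be 'analytic' or 'montecarlo'")


def naive_mutation_add_probability(p: int, set_size: int) -> float:
    """Chance a cost-agnostic toggle mutation adds (rather than removes).

    The toggled feature is uniform over the pool, so the mutation adds
    whenever it lands outside the current set: (p - set_size) / p.
    """
    if p < 1:
        raise ValueError("p must be at least 1")
    if not (0 <= set_size <= p):
        raise ValueError("need 0 <= set_size <= p")
    return (p - set_size) / p


# ---------------------------------------------------------------------------
# benchmark runner
# ---------------------------------------------------------------------------

METHOD_LABELS = (
    "fs",
    "cfs",
    "cfs-mean",
    "cfs-max",
    "fga",
    "cga",
    "filter-ttest",
    "filter-su",
)


def run_method(
    method: str,
    problem: SimulatedProblem,
    seed: int,
    ga_overrides: Optional[dict] = None,
    scorer: Optional[SubsetScorer] = None,
) -> SelectionResult:
    """Run one selection method on one realized problem.

    ``ga_overrides`` tunes the genetic-algorithm hyperparameters (e.g.
    smaller populations for quick studies) without touching the data
    conditions.
    """
    method = method.lower()
    train, model = problem.train, problem.cost_model
    if scorer is None:
        scorer = SubsetScorer(train)
    if method in ("fs", "cfs", "cfs-mean", "cfs-max"):
        cfg = GreedyConfig(strategy=method.replace("-", "."))
        return forward_select(train, model, cfg, scorer=scorer)
    if method in ("fga", "cga"):
        kwargs = {"variant": method, "seed": seed}
        if ga_overrides:
            kwargs.update(ga_overrides)
        cfg = GAConfig(**kwargs)
        return run_ga(train, model, cfg, scorer=scorer)
    if method == "filter-ttest":
        return filter_select_topdown(score_ttest(train), model)
    if method == "filter-su":
        return filter_select_topdown(score_symmetric_uncertainty(train), model)
    raise ValueError(f"unknown method {method!r}; choose from {METHOD_LABELS}")


def _evaluate_result(
    result: SelectionResult, problem: SimulatedProblem, scorer: SubsetScorer
) -> dict:
    rec = recovery_metrics(
        result.members, problem.relevance_mask, problem.train.feature_ids
    )
    fit = scorer.fit(result.members)
    auc = evaluate_auc(fit, problem.test)
    return {
        "auc": auc,
        "precision": rec.precision,
        "recall": rec.recall,
        "n_selected": rec.n_selected,
        "n_relevant_selected": rec.n_relevant_selected,
        "total_cost": result.total_cost,
        "aic": fit.aic,
    }


def run_benchmark(
    specs: Sequence[SettingSpec],
    methods: Sequence[str],
    master_seed: int,
    n_replicates: Optional[int] = None,
    ga_overrides: Optional[dict] = None,
    on_error: str = "record",
) -> pd.DataFrame:
    """Run a grid of (setting, method, replicate) selections.

    Returns a tidy long-format table with columns (setting, method,
    replicate, metric, value).  Per setting, two reference rows are added
    (replicate = -1): the budget-constraint recall cap min(1, gamma) and
    the random-selection precision; the random-selection recall is
    reported per replicate since it depends on the realized costs.

    Replicate ``b`` of every setting uses the seed ``master_seed + b`` so
    the whole table is reproducible from one integer; methods run on
    identical data within a replicate.  A method failure on one replicate
    is recorded as a ``failed`` metric rather than aborting the run.
    """
    if not specs or not methods:
        raise ValueError("need at least one setting and one method")
    rows: list[dict] = []

    def emit(setting: str, method: str, replicate: int, metric: str, value) -> None:
        rows.append(
            {
                "setting": setting,
                "method": method,
                "replicate": replicate,
                "metric": metric,
                "value": value,
            }
        )

    for spec in specs:
        emit(spec.label, "budget_constraint", -1, "recall_cap", min(1.0, spec.gamma))
        emit(
            spec.label,
            "random_selection",
            -1,
            "precision",
            random_precision(spec.p, spec.p_rel),
        )
        reps = spec.n_replicates if n_replicates is None else n_replicates
        for b in range(reps):
            rng = replicate_rng(master_seed, b)
            problem = realize_setting(spec, rng)
            model = problem.cost_model
            emit(
                spec.label,
                "random_selection",
                b,
                "recall",
                random_recall(
                    model.budget, float(model.costs.mean()), spec.p, spec.p_rel
                ),
            )
            scorer = SubsetScorer(problem.train)
            for method in methods:
                t0 = time.perf_counter()
                try:
                    result = run_method(
                        method,
                        problem,
                        seed=master_seed + b,
                        ga_overrides=ga_overrides,
                        scorer=scorer,
                    )
                    metrics = _evaluate_result(result, problem, scorer)
                except Exception as exc:  # noqa: BLE001 - recorded, not fatal
                    if on_error == "raise":
                        raise
                    emit(spec.label, method, b, "failed", repr(exc))
                    continue
                metrics["runtime_s"] = time.perf_counter() - t0
                for metric, value in metrics.items():
                    emit(spec.label, method, b, metric, value)
    df = pd.DataFrame(rows, columns=["setting", "method", "replicate", "metric", "value"])
    return df


def summarize_benchmark(table: pd.DataFrame) -> pd.DataFrame:
    """Aggregate the tidy table: mean and 0.05/0.95 quantiles per metric.

    Missing precision values (empty selections) are excluded from the
    aggregation; the ``failed`` diagnostic rows are dropped.
    """
    num = table[table["metric"] != "failed"].copy()
    num = num.dropna(subset=["value"])
    num["value"] = num["value"].astype(float)
    agg = (
        num.groupby(["setting", "method", "metric"])["value"]
        .agg(
            mean="mean",
            q05=lambda v: v.quantile(0.05),
            q95=lambda v: v.quantile(0.95),
            n="count",
        )
        .reset_index()
    )
    return agg
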