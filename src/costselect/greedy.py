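"""Budget-limited greedy forward selection.

Two flavours are provided.  Naive forward selection (``FS``) adds, in every
iteration, the affordable candidate with the largest raw AIC decrease —
costs only matter through the shrinking budget.  The benefit-cost-ratio
family (``cFS``) instead ranks affordable candidates by

    BCR_xi = (AIC(s) - AIC(s + X_i)) / (c_i + xi)

so that a cheap feature carrying the same information as an expensive one
is preferred.  ``xi = 0`` is the pure ratio (``cFS``); ``xi = mean(c)``
(``cFS.mean``) and ``xi = max(c)`` (``cFS.max``) soften the cost influence
towards the raw-benefit ordering, the limit as xi grows.

Both variants stop when the best affordable candidate no longer decreases
the AIC (an uninformative feature should never be added, however cheap) or
when no remaining candidate fits the residual budget.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .data import BUDGET_TOL, CostModel, Dataset, SelectionResult
from .scoring import SubsetScorer

__all__ = ["GreedyConfig", "resolve_xi", "bcr", "forward_select"]

STRATEGIES = ("fs", "cfs", "cfs.mean", "cfs.max", "cfs.custom")


@dataclass(frozen=True)
class GreedyConfig:
    """Configuration of the greedy search.

    strategy : one of ``fs``, ``cfs``, ``cfs.mean``, ``cfs.max``, ``cfs.custom``
    xi : trade-off offset in cost units, required for ``cfs.custom`` only
    max_features : optional hard cap on the number of selected features
    """

    strategy: str = "cfs"
    xi: Optional[float] = None
    max_features: Optional[int] = None

    def __post_init__(self) -> None:
        s = self.strategy.lower().replace("-", ".")
        if s not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}; choose from {STRATEGIES}")
        if s == "cfs.custom" and (self.xi is None or self.xi < 0):
            raise ValueError("cfs.custom requires a non-negative xi")
        object.__setattr__(self, "strategy", s)


def resolve_xi(strategy: str, costs: np.ndarray, xi: Optional[float] = None) -> float:
    """Resolve the trade-off offset for a strategy on the full cost vector.

    Evaluated once up front over all p costs, not on the shrinking
    candidate pool.
    """
    strategy = strategy.lower().replace("-", ".")
    if strategy in ("fs", "cfs"):
        return 0.0
    if strategy == "cfs.mean":
        return float(np.mean(costs))
    if strategy == "cfs.max":
        return float(np.max(costs))
    if strategy == "cfs.custom":
        if xi is None or xi < 0:
            raise ValueError("cfs.custom requires a non-negative xi")
        return float(xi)
    raise ValueError(f"unknown strategy {strategy!r}")


def bcr(aic_current: float, aic_candidate: float, cost: float, xi: float = 0.0) -> float:
    """Benefit-cost ratio of adding one feature: AIC gain per unit (cost + xi)."""
    denom = cost + xi
    if denom <= 0:
        raise ValueError("cost + xi must be positive")
    return (aic_current - aic_candidate) / denom


def forward_select(
    data: Dataset,
    model: CostModel,
    cfg: GreedyConfig = GreedyConfig(),
    scorer: Optional[SubsetScorer] = None,
) -> SelectionResult:
    """Greedy forward selection under a hard additive budget.

    In each iteration only candidates whose individual cost fits the
    remaining budget are evaluated; the best candidate by the configured
    criterion (raw AIC decrease for ``fs``, BCR_xi otherwise) is added if it
    improves the AIC.  Ties are broken by lowest feature index.  The
    returned set always satisfies the budget.
    """
    if scorer is None:
        scorer = SubsetScorer(data)
    ids = data.feature_ids
    costs = model.cost_vector(ids)
    xi = resolve_xi(cfg.strategy, costs, cfg.xi)
    use_ratio = cfg.strategy != "fs"

    selected: list[str] = []
    in_set = np.zeros(len(ids), dtype=bool)
    remaining = model.budget
    current = scorer.fit(())
    trace = [current.aic]

    while True:
        if cfg.max_features is not None and len(selected) >= cfg.max_features:
            break
        affordable = np.flatnonzero(~in_set & (costs <= remaining + BUDGET_TOL))
        if affordable.size == 0:
            break
        best_j = -1
        best_score = 0.0
        best_fit = None
        for j in affordable:
            cand = scorer.fit(selected + [ids[j]])
            gain = current.aic - cand.aic
            score = gain / (costs[j] + xi) if use_ratio else gain
            # strict > keeps the lowest-index candidate on ties
            if score > best_score and gain > 0:
                best_j, best_score, best_fit = j, score, cand
        if best_j < 0:
            break
        selected.append(ids[best_j])
        in_set[best_j] = True
        remaining -= costs[best_j]
        current = best_fit
        trace.append(current.aic)

    return SelectionResult(
        method=cfg.strategy,
        members=tuple(selected),
        total_cost=float(costs[in_set].sum()),
        score=current.aic,
        trace=trace,
        n_evaluations=scorer.n_evaluations,
        converged=current.converged,
        extra={"xi": xi},
    )
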