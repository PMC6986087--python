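"""Core domain types for budget-constrained feature selection.

A selection problem is described by three objects: a :class:`Dataset`
(feature matrix plus binary response), a :class:`CostModel` (one positive
acquisition cost per feature and a hard budget ``c_max``), and candidate
:class:`FeatureSet` objects whose summed member costs must not exceed the
budget.  The budget can be derived from a relative parameter ``gamma``
tying it to the total cost of the truly relevant features
(:func:`compute_budget`).

Costs are abstract, additive units — money, assay time, patient burden —
whatever disfavoured aspect of measuring a feature the analyst wants to
cap.  Costs must be strictly positive because the benefit-cost ratio used
by the greedy selector divides by them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

#: absolute tolerance used when comparing a set's cost against the budget,
#: so that sets filling the budget exactly are not excluded by round-off
BUDGET_TOL = 1e-9


def default_feature_ids(p: int) -> tuple[str, ...]:
    """Generate stable feature identifiers ``X1 .. Xp``."""
    return tuple(f"X{i + 1}" for i in range(p))


@dataclass(frozen=True)
class Dataset:
    """A sample-by-feature matrix with a binary response.

    Parameters
    ----------
    features : ndarray of shape (n, p)
        Real-valued feature matrix, one row per sample.
    response : ndarray of shape (n,)
        Binary class labels coded 0/1.
    feature_ids : tuple of str
        Unique identifier per column.
    role : {"train", "test"}
        Whether the data is used for model fitting or held-out evaluation.
    """

    features: np.ndarray
    response: np.ndarray
    feature_ids: tuple[str, ...]
    role: str = "train"

    def __post_init__(self) -> None:
        features = np.asarray(self.features, dtype=float)
        response = np.asarray(self.response)
        if features.ndim != 2:
            raise ValueError("features must be a 2-d matrix")
        n, p = features.shape
        if n < 1 or p < 1:
            raise ValueError("need at least one sample and one feature")
        if response.shape != (n,):
            raise ValueError(
                f"response length {response.shape} does not match {n} samples"
            )
        uniq = np.unique(response)
        if not np.isin(uniq, [0, 1]).all():
            raise ValueError("response must contain only 0/1 labels")
        ids = tuple(str(i) for i in self.feature_ids)
        if len(ids) != p:
            raise ValueError(f"{len(ids)} feature ids for {p} feature columns")
        if len(set(ids)) != p:
            raise ValueError("feature ids must be unique")
        if self.role not in ("train", "test"):
            raise ValueError(f"unknown role {self.role!r}")
        object.__setattr__(self, "features", features)
        object.__setattr__(self, "response", response.astype(np.int64))
        object.__setattr__(self, "feature_ids", ids)

    # -- convenience accessors -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def _index(self) -> dict[str, int]:
        try:
            return self.__dict__["_index_cache"]
        except KeyError:
            idx = {fid: j for j, fid in enumerate(self.feature_ids)}
            self.__dict__["_index_cache"] = idx
            return idx

    def index_of(self, members: Iterable[str]) -> np.ndarray:
        """Column indices of ``members``, raising on unknown ids."""
        idx = self._index
        out = []
        for fid in members:
            if fid not in idx:
                raise KeyError(f"unknown feature id {fid!r}")
            out.append(idx[fid])
        return np.asarray(out, dtype=np.intp)

    def columns(self, members: Iterable[str]) -> np.ndarray:
        """Sub-matrix of the given member features (column order = sorted index)."""
        cols = np.sort(self.index_of(members))
        return self.features[:, cols]

    def as_role(self, role: str) -> "Dataset":
        return replace(self, role=role)


@dataclass(frozen=True)
class CostModel:
    """Per-feature acquisition costs plus the hard budget ``c_max``.

    ``costs`` is a pandas Series indexed by feature id; every entry must be
    strictly positive.  ``gamma`` records, when known, the relative budget
    parameter the budget was derived from (purely informational here).
    """

    costs: pd.Series
    budget: float
    gamma: Optional[float] = None

    def __post_init__(self) -> None:
        costs = pd.Series(self.costs, dtype=float)
        costs.index = costs.index.map(str)
        if costs.index.has_duplicates:
            raise ValueError("duplicate feature ids in cost vector")
        if (costs <= 0).any():
            bad = costs.index[costs <= 0][0]
            raise ValueError(
                f"feature costs must be strictly positive (offending id {bad!r})"
            )
        if not np.isfinite(self.budget) or self.budget < 0:
            raise ValueError("budget must be a finite non-negative number")
        object.__setattr__(self, "costs", costs)
        object.__setattr__(self, "budget", float(self.budget))

    @property
    def feature_ids(self) -> tuple[str, ...]:
        return tuple(self.costs.index)

    def cost_of(self, feature_id: str) -> float:
        try:
            return float(self.costs.loc[feature_id])
        except KeyError:
            raise KeyError(f"unknown feature id {feature_id!r}") from None

    def cost_vector(self, feature_ids: Sequence[str]) -> np.ndarray:
        """Cost array aligned with ``feature_ids`` (errors on unknown ids)."""
        missing = [f for f in feature_ids if f not in self.costs.index]
        if missing:
            raise KeyError(f"unknown feature id {missing[0]!r}")
        return self.costs.loc[list(feature_ids)].to_numpy(dtype=float)


@dataclass(frozen=True)
class FeatureSet:
    """A candidate subset ``s`` with its total cost and optional score."""

    members: frozenset[str]
    total_cost: float
    score: Optional[float] = None

    @classmethod
    def from_members(
        cls, members: Iterable[str], model: CostModel, score: Optional[float] = None
    ) -> "FeatureSet":
        members = frozenset(str(m) for m in members)
        return cls(members=members, total_cost=total_cost(members, model), score=score)

    @property
    def size(self) -> int:
        return len(self.members)

    def sorted_members(self) -> tuple[str, ...]:
        return tuple(sorted(self.members))


@dataclass
class SelectionResult:
    """Outcome of one feature-selection run.

    ``trace`` holds the method's score path: per-step AIC for the greedy
    selectors, best fitness per generation for the genetic variants.
    """

    method: str
    members: tuple[str, ...]
    total_cost: float
    score: Optional[float]
    trace: list = field(default_factory=list)
    n_evaluations: int = 0
    seed: Optional[int] = None
    feasible: bool = True
    converged: bool = True
    extra: dict = field(default_factory=dict)

    @property
    def n_selected(self) -> int:
        return len(self.members)

    def feature_set(self, model: CostModel) -> FeatureSet:
        return FeatureSet.from_members(self.members, model, score=self.score)


# ---------------------------------------------------------------------------
# cost sampling
# ---------------------------------------------------------------------------


def sample_costs_uniform(p: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``p`` i.i.d. costs from Uniform(0.1, 1)."""
    if p < 0:
        raise ValueError("p must be non-negative")
    return rng.uniform(0.1, 1.0, size=p)


def sample_costs_effect_dependent(
    relevance_mask: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Costs correlated with relevance: relevant ~ U(0.4, 1), noise ~ U(0.1, 0.7).

    Relevant features then have mean cost 0.7 versus 0.4 for noise features,
    so valuable information is on average more expensive to acquire.
    """
    mask = np.asarray(relevance_mask, dtype=bool)
    p = mask.size
    costs = np.empty(p)
    n_rel = int(mask.sum())
    costs[mask] = rng.uniform(0.4, 1.0, size=n_rel)
    costs[~mask] = rng.uniform(0.1, 0.7, size=p - n_rel)
    return costs


def sample_costs_correlated(mu: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Costs positively correlated with effect size: c_i ~ U(0.1 + mu_i/2, 0.5 + mu_i/2)."""
    mu = np.asarray(mu, dtype=float)
    if (mu < 0).any():
        raise ValueError("effect sizes must be non-negative")
    return rng.uniform(0.1 + mu / 2, 0.5 + mu / 2)


# ---------------------------------------------------------------------------
# budget
# ---------------------------------------------------------------------------


def compute_budget(
    costs: np.ndarray, relevance_mask: np.ndarray, gamma: float
) -> float:
    """Budget ``c_max`` relative to the total cost of relevant features.

    For ``gamma <= 1`` the budget is the summed cost of the relevant features
    whose cost does not exceed the gamma-quantile of the relevant-cost
    distribution, i.e. at most the cheapest gamma-fraction of the relevant
    information fits in.  The quantile is the inclusive empirical one: the
    order statistic at position ``ceil(gamma * p_rel)``, so gamma = 0.5 with an
    even relevant count admits exactly the cheapest half.

    For ``gamma > 1`` the budget is the full relevant cost plus headroom for
    ``(gamma - 1) * p_rel`` additional features at the overall mean cost.
    """
    costs = np.asarray(costs, dtype=float)
    mask = np.asarray(relevance_mask, dtype=bool)
    if mask.shape != costs.shape:
        raise ValueError("relevance mask and cost vector lengths differ")
    if gamma < 0:
        raise ValueError("gamma must be non-negative")
    rel = costs[mask]
    if gamma > 0 and rel.size == 0:
        raise ValueError("no relevant features: budget undefined for gamma > 0")
    if gamma == 0 or rel.size == 0:
        return 0.0
    if gamma <= 1:
        k = math.ceil(gamma * rel.size)
        if k == 0:
            return 0.0
        q = np.sort(rel)[k - 1]
        return float(rel[rel <= q].sum())
    c_bar = costs.mean()
    return float(rel.sum() + (gamma - 1.0) * c_bar * rel.size)


def total_cost(members: Iterable[str] | FeatureSet, model: CostModel) -> float:
    """Summed cost of the member features (unknown ids raise KeyError)."""
    if isinstance(members, FeatureSet):
        members = members.members
    return float(sum(model.cost_of(m) for m in members))


def within_budget(
    members: Iterable[str] | FeatureSet, model: CostModel, tol: float = BUDGET_TOL
) -> bool:
    """True when the member costs sum to at most the budget (inclusive boundary)."""
    return total_cost(members, model) <= model.budget + tol
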