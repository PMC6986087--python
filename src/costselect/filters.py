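"""Filter baselines with budget-constrained top-down subset construction.

Filters assign every feature an importance score independently of any
multivariate model, then build the final subset by walking the ranking
top-down: each feature is added if its cost still fits the remaining
budget and skipped otherwise, until no remaining feature fits or the next
feature's importance crosses an optional usefulness threshold.

Two scorers ship with the package — the two-sample Welch t-test p-value
(lower is better) and symmetric uncertainty after equal-frequency
discretization (higher is better) — plus an adapter that wraps any
caller-supplied per-feature importance function, e.g. mutual-information
or tree-impurity scorers from other libraries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import mutual_info_score

from .data import BUDGET_TOL, CostModel, Dataset, SelectionResult

__all__ = [
    "ImportanceRanking",
    "score_ttest",
    "score_symmetric_uncertainty",
    "score_adapter",
    "filter_select_topdown",
    "DEFAULT_THRESHOLDS",
    "USE_DEFAULT_THRESHOLD",
]

#: default importance thresholds for the shipped filters; features whose
#: importance crosses the threshold stop the top-down walk
DEFAULT_THRESHOLDS = {"ttest": 0.05, "symmetric_uncertainty": 1e-6}

#: sentinel: look the threshold up in DEFAULT_THRESHOLDS by scorer label
USE_DEFAULT_THRESHOLD = "default"


@dataclass(frozen=True)
class ImportanceRanking:
    """Per-feature importance scores with an explicit direction.

    ``scores`` is aligned with ``feature_ids``; NaN marks a feature whose
    score could not be computed (e.g. zero variance in both classes) —
    such features rank last.
    """

    scores: np.ndarray
    direction: str  # "higher" | "lower"
    method_label: str
    feature_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        if scores.shape != (len(self.feature_ids),):
            raise ValueError("one score per feature required")
        if self.direction not in ("higher", "lower"):
            raise ValueError("direction must be 'higher' or 'lower'")
        object.__setattr__(self, "scores", scores)
        object.__setattr__(self, "feature_ids", tuple(self.feature_ids))

    def rank_order(self) -> np.ndarray:
        """Feature indices from most to least important.

        NaN scores go last; ties are broken by feature index (stable sort).
        """
        key = self.scores.copy()
        if self.direction == "higher":
            key = -key
        key[np.isnan(self.scores)] = np.inf
        return np.argsort(key, kind="stable")


def score_ttest(data: Dataset) -> ImportanceRanking:
    """Welch two-sample t-test p-value per feature (lower is better).

    Features with zero variance in both response groups get a NaN score
    and rank last.
    """
    y = data.response
    if (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise ValueError("both classes need at least two samples for the t-test")
    g1 = data.features[y == 1]
    g0 = data.features[y == 0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # 0/0 for degenerate columns -> nan
        res = stats.ttest_ind(g1, g0, equal_var=False, axis=0)
    pvals = np.asarray(res.pvalue, dtype=float)
    return ImportanceRanking(
        scores=pvals,
        direction="lower",
        method_label="ttest",
        feature_ids=data.feature_ids,
    )


def _symmetric_uncertainty(x: np.ndarray, y: np.ndarray, bins: int) -> float:
    """SU(X;Y) = 2 I(X;Y) / (H(X) + H(Y)) after equal-frequency binning of X."""
    codes, edges = pd.qcut(x, q=bins, retbins=True, labels=False, duplicates="drop")
    if len(edges) <= 2:  # feature collapsed to a single bin
        return 0.0
    mi = mutual_info_score(codes, y)
    h_x = stats.entropy(np.bincount(codes.astype(int)))
    h_y = stats.entropy(np.bincount(y))
    denom = h_x + h_y
    if denom <= 0:
        return 0.0
    return float(2.0 * mi / denom)


def score_symmetric_uncertainty(data: Dataset, bins: int = 10) -> ImportanceRanking:
    """Symmetric uncertainty between each discretized feature and the response.

    Each feature is cut into ``bins`` equal-frequency bins (default 10);
    SU is the mutual information normalized by the mean entropy, in [0, 1],
    higher is better.  Degenerate features score 0.
    """
    if bins < 2:
        raise ValueError("need at least two bins")
    y = data.response
    scores = np.array(
        [_symmetric_uncertainty(data.features[:, j], y, bins) for j in range(data.n_features)]
    )
    return ImportanceRanking(
        scores=scores,
        direction="higher",
        method_label="symmetric_uncertainty",
        feature_ids=data.feature_ids,
    )


def score_adapter(
    data: Dataset,
    scorer: Callable[[np.ndarray, np.ndarray], np.ndarray],
    method_label: str = "external",
    direction: str = "higher",
) -> ImportanceRanking:
    """Wrap an external importance function into an :class:`ImportanceRanking`.

    ``scorer(features, response)`` must return one finite value per
    feature; non-finite values and length mismatches are rejected with the
    offending feature id.
    """
    raw = np.asarray(scorer(data.features, data.response), dtype=float)
    if raw.shape != (data.n_features,):
        raise ValueError(
            f"scorer returned {raw.shape} values for {data.n_features} features"
        )
    bad = np.flatnonzero(~np.isfinite(raw))
    if bad.size:
        raise ValueError(
            f"scorer returned a non-finite importance for feature "
            f"{data.feature_ids[bad[0]]!r}"
        )
    return ImportanceRanking(
        scores=raw,
        direction=direction,
        method_label=method_label,
        feature_ids=data.feature_ids,
    )


def _crosses_threshold(score: float, direction: str, threshold: float) -> bool:
    if np.isnan(score):
        return True
    if direction == "lower":
        return score > threshold
    return score < threshold


def filter_select_topdown(
    ranking: ImportanceRanking,
    model: CostModel,
    threshold: float | None | str = USE_DEFAULT_THRESHOLD,
    stop_at_first_unaffordable: bool = False,
) -> SelectionResult:
    """Budget-constrained top-down selection from an importance ranking.

    Features are visited in rank order.  Each is added if its cost fits
    the remaining budget; an unaffordable feature is skipped and never
    blocks later affordable ones (set ``stop_at_first_unaffordable`` for
    the stricter reading that terminates the walk there).  The walk also
    stops when the next feature's importance crosses ``threshold``.

    By default the shipped scorers use their conventional thresholds (0.05
    for the t-test filter, 1e-6 for symmetric uncertainty) and other
    rankings use none; pass an explicit number to override, or ``None`` to
    disable the threshold entirely.
    """
    if threshold == USE_DEFAULT_THRESHOLD:
        threshold = DEFAULT_THRESHOLDS.get(ranking.method_label)
    ids = ranking.feature_ids
    costs = model.cost_vector(ids)
    selected: list[str] = []
    remaining = model.budget
    spent = 0.0
    trace: list[float] = []
    for j in ranking.rank_order():
        if threshold is not None and _crosses_threshold(
            float(ranking.scores[j]), ranking.direction, threshold
        ):
            break
        if costs[j] > remaining + BUDGET_TOL:
            if stop_at_first_unaffordable:
                break
            continue
        selected.append(ids[j])
        remaining -= costs[j]
        spent += costs[j]
        trace.append(float(ranking.scores[j]))
    return SelectionResult(
        method=f"filter-{ranking.method_label}",
        members=tuple(selected),
        total_cost=spent,
        score=None,
        trace=trace,
        extra={"threshold": threshold},
    )
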