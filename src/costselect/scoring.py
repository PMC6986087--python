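"""Model scoring: AIC of a logistic fit on a candidate subset, and test AUC.

Every selector in this package scores a candidate feature subset ``s`` by
the Akaike Information Criterion of a logistic regression of the binary
response on the member features plus an intercept:

    AIC(s) = 2 (|s| + 1) - 2 loglik

Lower is better; the 2k penalty provides the implicit stopping rule of the
greedy search.  The fit is a plain Newton/IRLS iteration — subsets are
small (a handful to a few dozen features), so each fit is a sequence of
tiny weighted least-squares solves, which keeps population-based searches
with tens of thousands of fitness evaluations tractable.  Statistical
correctness of the fit is cross-checked against an independent maximum
likelihood implementation in the test suite.

Complete separation makes the MLE diverge; the iteration is capped and the
achieved penalized likelihood is returned with ``converged=False`` so that
a search never aborts on one pathological candidate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy.special import expit
from sklearn.metrics import roc_auc_score

from .data import Dataset, FeatureSet

__all__ = ["ScoredFit", "fit_aic", "evaluate_auc", "SubsetScorer"]


@dataclass(frozen=True)
class ScoredFit:
    """A fitted logistic model on one candidate subset.

    ``coefficients`` is ordered (intercept, then members sorted by column
    index in the training data).
    """

    feature_set: FeatureSet
    aic: float
    log_likelihood: float
    coefficients: np.ndarray
    member_order: tuple[str, ...]
    converged: bool


def _newton_logistic(
    X: np.ndarray, y: np.ndarray, max_iter: int = 100, tol: float = 1e-8
) -> tuple[np.ndarray, float, bool]:
    """IRLS fit of a logistic regression; X already includes the intercept.

    Returns (beta, log-likelihood, converged).  Rank-deficient designs
    (duplicated columns) are handled by the least-squares solve, which picks
    the minimum-norm Newton step.
    """
    n, k = X.shape
    beta = np.zeros(k)
    ybar = y.mean()
    if 0.0 < ybar < 1.0:
        beta[0] = np.log(ybar / (1.0 - ybar))
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        p = expit(eta)
        w = p * (1.0 - p)
        # guard against vanishing weights under separation
        w = np.clip(w, 1e-10, None)
        z = eta + (y - p) / w
        sw = np.sqrt(w)
        beta_new, *_ = np.linalg.lstsq(X * sw[:, None], z * sw, rcond=None)
        step = np.max(np.abs(beta_new - beta))
        beta = beta_new
        if step < tol:
            converged = True
            break
    eta = X @ beta
    # stable Bernoulli log-likelihood: y*eta - log(1 + exp(eta))
    llf = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
    return beta, llf, converged


def fit_aic(
    data: Dataset,
    members: Iterable[str] | FeatureSet,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> ScoredFit:
    """Fit logistic(response ~ intercept + members) and return its AIC.

    The AIC parameter count is |members| + 1, counting the intercept.
    Duplicate member ids are collapsed (a set has no multiplicity); a
    rank-deficient design from perfectly collinear columns still yields the
    achieved likelihood.
    """
    if data.role != "train":
        raise ValueError("fit_aic expects a train-role dataset")
    if isinstance(members, FeatureSet):
        member_ids = members.members
        fset = members
    else:
        member_ids = frozenset(str(m) for m in members)
        fset = None
    cols = np.sort(data.index_of(member_ids))
    order = tuple(data.feature_ids[j] for j in cols)
    n = data.n_samples
    X = np.column_stack([np.ones(n), data.features[:, cols]])
    beta, llf, converged = _newton_logistic(
        X, data.response.astype(float), max_iter=max_iter, tol=tol
    )
    k = len(member_ids) + 1
    aic = 2.0 * k - 2.0 * llf
    if fset is None:
        fset = FeatureSet(members=member_ids, total_cost=float("nan"), score=aic)
    return ScoredFit(
        feature_set=fset,
        aic=float(aic),
        log_likelihood=llf,
        coefficients=beta,
        member_order=order,
        converged=converged,
    )


def linear_predictor(fit: ScoredFit, data: Dataset) -> np.ndarray:
    """Evaluate the fitted linear predictor on another dataset."""
    cols = data.index_of(fit.member_order)
    X = np.column_stack([np.ones(data.n_samples), data.features[:, cols]])
    return X @ fit.coefficients


def evaluate_auc(fit: ScoredFit, test: Dataset) -> float:
    """Rank-based AUC of the fitted linear predictor on held-out data.

    Equivalent to the normalized Mann-Whitney U statistic; tied scores
    contribute 1/2 (midrank convention).
    """
    y = test.response
    if y.min() == y.max():
        raise ValueError("test labels contain a single class; AUC undefined")
    scores = linear_predictor(fit, test)
    return float(roc_auc_score(y, scores))


class SubsetScorer:
    """Memoizing AIC evaluator for a fixed training dataset.

    Population searches revisit the same subsets constantly; caching by
    member set turns repeat evaluations into dictionary lookups.  The
    ``n_evaluations`` counter counts actual model fits only.
    """

    def __init__(self, data: Dataset, max_iter: int = 100, tol: float = 1e-8):
        if data.role != "train":
            raise ValueError("SubsetScorer expects a train-role dataset")
        self.data = data
        self.max_iter = max_iter
        self.tol = tol
        self._cache: dict[frozenset, ScoredFit] = {}
        self.n_evaluations = 0

    def fit(self, members: Iterable[str] | FeatureSet) -> ScoredFit:
        if isinstance(members, FeatureSet):
            key = members.members
        else:
            key = frozenset(str(m) for m in members)
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        fit = fit_aic(self.data, key, max_iter=self.max_iter, tol=self.tol)
        self._cache[key] = fit
        self.n_evaluations += 1
        return fit

    def aic(self, members: Iterable[str] | FeatureSet) -> float:
        return self.fit(members).aic
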