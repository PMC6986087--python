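"""Synthetic simulation framework for budget-constrained selection studies.

Each :class:`SettingSpec` fixes a binary-classification scenario by the
relative budget ``gamma``, the feature count ``p``, the number of truly
relevant features ``p_rel``, the effect size ``beta`` (in feature-sd
units), and the rules for cost sampling, covariance, feature distribution
and response generation.  The eleven shipped presets A-K span small to
high-dimensional pools (p = 30 .. 1500), constant and graded effect sizes,
independent and correlated features, effect-dependent costs, and a
heavy-tailed feature distribution:

    A (1/2,   30, 18, 0.3)   B (2/3,  30,  3, 1)     C (1/3, 300, 30, 0.5)
    D (2/3,  300,  3, 0.5)   E (2,  1500, 15, 0.5)   F (1/2, 1500, 20, 0.5)
    G: logistic response on correlated features       H: effect-dependent costs
    I: graded effects 1/30..1    J: I + cost-effect correlation
    K: heavy-tail normal scale mixture

The default response model is class-conditional: y ~ Bernoulli(0.5), then
X | y=1 ~ N_p(mu, Sigma) and X | y=0 ~ N_p(0, Sigma).  Setting G instead
draws X ~ N_p(0, Sigma) and y_i ~ Bernoulli(expit(x_i' mu)), which avoids
the artificial perfect separability that a non-identity covariance causes
in the class-conditional construction.

Setting G's original covariance was estimated from a proprietary
metabolomics dataset and is not available; a synthetic block-exchangeable
substitute (unit variances, within-block correlation ``rho``) stands in to
emulate highly correlated covariables.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd

from .data import (
    CostModel,
    Dataset,
    compute_budget,
    default_feature_ids,
    sample_costs_correlated,
    sample_costs_effect_dependent,
    sample_costs_uniform,
)

__all__ = [
    "SettingSpec",
    "SimulatedProblem",
    "SETTINGS",
    "get_setting",
    "build_mu",
    "make_correlated_covariance",
    "sample_heavy_tail",
    "generate_class_conditional",
    "generate_logistic",
    "realize_setting",
    "replicate_rng",
]


@dataclass(frozen=True)
class SettingSpec:
    """Parameters of one simulation setting.

    ``beta`` is either a constant effect size or the string ``"sequence"``
    for the graded equidistant effects p_rel/p_rel, ..., 2/p_rel, 1/p_rel.
    """

    label: str
    gamma: float
    p: int
    p_rel: int
    beta: float | str
    n_train: int = 500
    n_test: int = 10_000
    n_replicates: int = 100
    cost_rule: str = "uniform"  # uniform | effect_dependent | correlated
    covariance_rule: str = "identity"  # identity | correlated_substitute
    distribution_rule: str = "normal"  # normal | heavy_tail_mixture
    generation_model: str = "class_conditional"  # class_conditional | logistic
    block_size: int = 5
    rho: float = 0.7
    heavy_tail_sd: float = 5.0

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError("gamma must be non-negative")
        if not (0 <= self.p_rel <= self.p):
            raise ValueError("need 0 <= p_rel <= p")
        if isinstance(self.beta, str):
            if self.beta != "sequence":
                raise ValueError("beta must be a number or 'sequence'")
        elif self.beta < 0:
            raise ValueError("beta must be non-negative")
        for fld, allowed in (
            ("cost_rule", ("uniform", "effect_dependent", "correlated")),
            ("covariance_rule", ("identity", "correlated_substitute")),
            ("distribution_rule", ("normal", "heavy_tail_mixture")),
            ("generation_model", ("class_conditional", "logistic")),
        ):
            if getattr(self, fld) not in allowed:
                raise ValueError(f"{fld} must be one of {allowed}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SettingSpec":
        return cls(**d)

    def scaled(self, **overrides) -> "SettingSpec":
        """A copy with some parameters overridden (e.g. smaller sizes)."""
        return replace(self, **overrides)


@dataclass(frozen=True)
class SimulatedProblem:
    """One realized replicate: train/test data, costs + budget, ground truth."""

    train: Dataset
    test: Dataset
    cost_model: CostModel
    relevance_mask: np.ndarray
    spec: SettingSpec


SETTINGS: dict[str, SettingSpec] = {
    "A": SettingSpec("A", 1 / 2, 30, 18, 0.3),
    "B": SettingSpec("B", 2 / 3, 30, 3, 1.0),
    "C": SettingSpec("C", 1 / 3, 300, 30, 0.5),
    "D": SettingSpec("D", 2 / 3, 300, 3, 0.5),
    "E": SettingSpec("E", 2.0, 1500, 15, 0.5),
    "F": SettingSpec("F", 1 / 2, 1500, 20, 0.5),
    "G": SettingSpec(
        "G",
        1 / 3,
        300,
        30,
        0.3,
        covariance_rule="correlated_substitute",
        generation_model="logistic",
    ),
    "H": SettingSpec("H", 1 / 3, 300, 30, 0.5, cost_rule="effect_dependent"),
    "I": SettingSpec("I", 1 / 3, 300, 30, "sequence"),
    "J": SettingSpec("J", 1 / 3, 300, 30, "sequence", cost_rule="correlated"),
    "K": SettingSpec("K", 1 / 3, 300, 30, 0.5, distribution_rule="heavy_tail_mixture"),
}


def get_setting(label: str) -> SettingSpec:
    try:
        return SETTINGS[label.upper()]
    except KeyError:
        raise ValueError(
            f"unknown setting {label!r}; available: {', '.join(SETTINGS)}"
        ) from None


def build_mu(spec: SettingSpec) -> np.ndarray:
    """Mean-shift (effect) vector of length p.

    Constant-beta settings put ``beta`` on the first p_rel entries.  The
    graded variant uses the descending equidistant sequence
    p_rel/p_rel, ..., 2/p_rel, 1/p_rel on the relevant block.  Noise
    entries are 0.
    """
    mu = np.zeros(spec.p)
    if spec.p_rel == 0:
        return mu
    if spec.beta == "sequence":
        mu[: spec.p_rel] = np.arange(spec.p_rel, 0, -1) / spec.p_rel
    else:
        mu[: spec.p_rel] = float(spec.beta)
    return mu


def relevance_mask(spec: SettingSpec) -> np.ndarray:
    return build_mu(spec) > 0


def make_correlated_covariance(
    p: int, block_size: int = 5, rho: float = 0.7
) -> np.ndarray:
    """Synthetic block-exchangeable covariance (unit variances).

    Features are grouped into consecutive blocks of ``block_size`` with
    pairwise correlation ``rho`` inside a block and independence across
    blocks; the final block may be shorter.  Positive definite for
    |rho| < 1 (block eigenvalues 1 + (b-1) rho and 1 - rho).
    """
    if p < 1:
        raise ValueError("p must be at least 1")
    if not (-1.0 < rho < 1.0):
        raise ValueError("rho must lie strictly between -1 and 1")
    sigma = np.eye(p)
    if block_size <= 1 or rho == 0.0:
        return sigma
    for start in range(0, p, block_size):
        stop = min(start + block_size, p)
        sigma[start:stop, start:stop] = rho
        np.fill_diagonal(sigma[start:stop, start:stop], 1.0)
    return sigma


def sample_heavy_tail(
    mu: np.ndarray,
    n: int,
    rng: np.random.Generator,
    tail_sd: float = 5.0,
    tail_prob: float = 0.1,
) -> np.ndarray:
    """Heavy-tailed features: a per-cell normal scale mixture.

    Each cell is drawn from N(mu_i, 1) with probability 1 - tail_prob and
    from N(mu_i, tail_sd^2) otherwise, keeping the marginal mean at mu_i
    while adding extreme values (variance 0.9 + 0.1 tail_sd^2 = 3.4 at the
    defaults; positive excess kurtosis).  ``tail_sd`` is a standard
    deviation.
    """
    mu = np.asarray(mu, dtype=float)
    if n < 1:
        raise ValueError("n must be at least 1")
    z = rng.standard_normal((n, mu.size))
    scale = np.where(rng.random((n, mu.size)) < tail_prob, tail_sd, 1.0)
    return mu[None, :] + z * scale


def _draw_features(
    spec: SettingSpec, n: int, rng: np.random.Generator, chol: Optional[np.ndarray]
) -> np.ndarray:
    """Zero-mean feature noise matrix under the spec's distribution rule."""
    if spec.distribution_rule == "heavy_tail_mixture":
        return sample_heavy_tail(
            np.zeros(spec.p), n, rng, tail_sd=spec.heavy_tail_sd
        )
    z = rng.standard_normal((n, spec.p))
    if chol is not None:
        z = z @ chol.T
    return z


def _cholesky(spec: SettingSpec) -> Optional[np.ndarray]:
    if spec.covariance_rule == "identity":
        return None
    sigma = make_correlated_covariance(spec.p, spec.block_size, spec.rho)
    try:
        return np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError:
        raise ValueError("covariance matrix is not positive definite") from None


def generate_class_conditional(
    spec: SettingSpec, rng: np.random.Generator, n: Optional[int] = None, role: str = "train"
) -> Dataset:
    """Class-conditional draw: y ~ Bernoulli(0.5), X | y shifted by mu."""
    n = spec.n_train if n is None else n
    mu = build_mu(spec)
    chol = _cholesky(spec)
    y = (rng.random(n) < 0.5).astype(np.int64)
    X = _draw_features(spec, n, rng, chol)
    X[y == 1] += mu[None, :]
    return Dataset(
        features=X, response=y, feature_ids=default_feature_ids(spec.p), role=role
    )


def generate_logistic(
    spec: SettingSpec, rng: np.random.Generator, n: Optional[int] = None, role: str = "train"
) -> Dataset:
    """Logistic draw: X ~ N_p(0, Sigma), y_i ~ Bernoulli(expit(x_i' mu))."""
    n = spec.n_train if n is None else n
    mu = build_mu(spec)
    chol = _cholesky(spec)
    X = _draw_features(spec, n, rng, chol)
    eta = X @ mu
    pi = 1.0 / (1.0 + np.exp(-eta))
    y = (rng.random(n) < pi).astype(np.int64)
    return Dataset(
        features=X, response=y, feature_ids=default_feature_ids(spec.p), role=role
    )


def _generate(spec: SettingSpec, rng: np.random.Generator, n: int, role: str) -> Dataset:
    if spec.generation_model == "logistic":
        return generate_logistic(spec, rng, n=n, role=role)
    return generate_class_conditional(spec, rng, n=n, role=role)


def sample_costs(spec: SettingSpec, rng: np.random.Generator) -> np.ndarray:
    """Per-feature costs under the spec's cost rule."""
    if spec.cost_rule == "uniform":
        return sample_costs_uniform(spec.p, rng)
    if spec.cost_rule == "effect_dependent":
        return sample_costs_effect_dependent(relevance_mask(spec), rng)
    return sample_costs_correlated(build_mu(spec), rng)


def realize_setting(
    spec: SettingSpec, rng: np.random.Generator
) -> SimulatedProblem:
    """Draw one full replicate: costs, budget, train and test data.

    Costs are drawn first, the budget follows from the gamma rule on the
    relevant costs, then train (n_train) and test (n_test) sets are drawn
    independently from the same distribution.
    """
    mask = relevance_mask(spec)
    costs = sample_costs(spec, rng)
    budget = compute_budget(costs, mask, spec.gamma)
    ids = default_feature_ids(spec.p)
    cost_model = CostModel(
        costs=pd.Series(costs, index=ids), budget=budget, gamma=spec.gamma
    )
    train = _generate(spec, rng, spec.n_train, "train")
    test = _generate(spec, rng, spec.n_test, "test")
    return SimulatedProblem(
        train=train, test=test, cost_model=cost_model, relevance_mask=mask, spec=spec
    )


def replicate_rng(master_seed: int, replicate: int) -> np.random.Generator:
    """Independent, reproducible stream for replicate ``b``: seed = master + b."""
    return np.random.default_rng(int(master_seed) + int(replicate))
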