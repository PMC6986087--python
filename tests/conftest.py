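import numpy as np
import pandas as pd
import pytest

from costselect.data import CostModel, Dataset, default_feature_ids
from costselect.simulate import SettingSpec, realize_setting


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def balanced_dataset():
    """n=500 balanced 0/1 response with 3 standard-normal noise features."""
    gen = np.random.default_rng(7)
    y = np.r_[np.zeros(250, dtype=int), np.ones(250, dtype=int)]
    X = gen.standard_normal((500, 3))
    return Dataset(features=X, response=y, feature_ids=default_feature_ids(3))


@pytest.fixture
def informative_dataset():
    """One strongly separating feature (group shift 1 sd) plus two noise ones."""
    gen = np.random.default_rng(11)
    y = (gen.random(500) < 0.5).astype(int)
    X = gen.standard_normal((500, 3))
    X[:, 0] += y  # beta = 1 group separation on the first feature
    return Dataset(features=X, response=y, feature_ids=default_feature_ids(3))


@pytest.fixture
def unit_cost_model():
    ids = default_feature_ids(3)
    return CostModel(costs=pd.Series(1.0, index=ids), budget=2.0)


@pytest.fixture
def toy_problem():
    """A small realized setting (p=10, tight budget) for oracle comparisons."""
    spec = SettingSpec("toy", gamma=0.5, p=10, p_rel=4, beta=0.8,
                       n_train=150, n_test=400)
    return realize_setting(spec, np.random.default_rng(5))


def make_cost_model(costs, budget, gamma=None):
    ids = default_feature_ids(len(costs))
    return CostModel(costs=pd.Series(costs, index=ids), budget=budget, gamma=gamma)
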