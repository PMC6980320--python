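import numpy as np
import pytest

import treestack as ts


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_config():
    """A small but structurally complete scenario: K=4, V=2, p=15."""
    return ts.ScenarioConfig(
        K=4, V=2, n_per_study=40, p=15, m=3, mtry=5,
        heterogeneity=ts.HeterogeneityProfile(l_low=0.25, l_high=1.0),
        n_iterations=2, master_seed=1,
    )


@pytest.fixture(scope="session")
def small_collection(small_config):
    collection, model = ts.build_collection(small_config, 12345)
    return collection, model


@pytest.fixture(scope="session")
def small_fitted(small_config, small_collection):
    collection, _ = small_collection
    return ts.fit_all_strategies(
        collection, m=small_config.m, mtry=small_config.mtry,
        stacking=ts.StackingConfig(n_lambda=20, cv_folds=5), seed=99,
    )
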