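import numpy as np
import pytest

from tfnn import synthetic
from tfnn.training import LossConfig, ModelConfig, fit


@pytest.fixture(scope="session")
def default_cohort():
    """The documented planted-rule benchmark cohort (n=2000, H=8, rho=0.1)."""
    return synthetic.generate(synthetic.default_fixture_spec())


@pytest.fixture(scope="session")
def trained_fixture_model(default_cohort):
    """One model trained on the full default cohort with default settings;
    shared by rule-recovery and extraction tests."""
    c = default_cohort
    hist = fit(c.X, c.y, ModelConfig(n_rules=10), LossConfig(seed=0),
               feature_names=c.spec.feature_names)
    return hist.state


@pytest.fixture()
def small_state():
    """An untrained tiny model for structural and gradient tests."""
    from tfnn.network import init_model

    return init_model(3, 3, 2, 2, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
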