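import numpy as np
import pandas as pd
import pytest

from spatsel import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def default_study():
    """One full synthetic study under the default conditions (seed 7)."""
    return simulate_study(SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def null_study():
    """Study with no true effects and no random-intercept variation."""
    cfg = SimulationConfig(seed=11, true_beta={}, random_intercept_sd=0.0)
    return simulate_study(cfg, include_strip=False)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_strong_effect_data(seed, n=200, p=5, beta=2.0):
    """Logistic data with one strong standardized effect and p-1 nulls."""
    g = np.random.default_rng(seed)
    X = pd.DataFrame(
        g.standard_normal((n, p)), columns=[f"x{i}" for i in range(p)]
    )
    lp = beta * X["x0"].to_numpy()
    y = g.binomial(1, 1.0 / (1.0 + np.exp(-lp)))
    return X, y
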