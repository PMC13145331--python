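import numpy as np
import pytest

from metaipm import inference, synthetic


@pytest.fixture(scope="session")
def small_sim():
    """12-year synthetic study with modest marking effort (fast tests)."""
    cfg = synthetic.SimulationConfig(n_years=12, seed=42)
    cfg.releases[:, :3, :] = 20
    data, truth = synthetic.simulate(cfg)
    return data, truth


@pytest.fixture(scope="session")
def default_sim():
    """Default-scale synthetic study: 4 groups, 39 winters."""
    cfg = synthetic.default_config(seed=7)
    data, truth = synthetic.simulate(cfg)
    return data, truth


@pytest.fixture(scope="session")
def fitted_small(small_sim):
    """A short posterior fit on the 12-year study, for API-level tests."""
    data, truth = small_sim
    mc = inference.MCMCConfig(n_chains=2, n_iter=900, n_burn=300, thin=3,
                              seed=11)
    return inference.fit_mcmc(data, config=mc), data, truth


@pytest.fixture
def rng():
    return np.random.default_rng(0)
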