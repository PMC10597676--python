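import numpy as np
import pytest

import sizespectra as ss


@pytest.fixture(scope="session")
def default_cfg():
    return ss.default_config()


@pytest.fixture(scope="session")
def default_sim(default_cfg):
    return ss.Simulation(default_cfg)


@pytest.fixture(scope="session")
def short_run():
    """A short default-trait run shared by plumbing tests."""
    cfg = ss.default_config(years=12, averaging_years=6)
    sim = ss.Simulation(cfg)
    return sim, ss.run_simulation(cfg, sim=sim)


@pytest.fixture()
def rng():
    return np.random.default_rng(17)
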