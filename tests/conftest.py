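import numpy as np
import pytest

from dcehybrid import (
    SimConfig,
    tissue_conc_tofts,
    tissue_conc_unidirectional,
)


@pytest.fixture(scope="session")
def sim_config() -> SimConfig:
    """Default study conditions (truths, baseline, sampling, AIF)."""
    return SimConfig()


@pytest.fixture(scope="session")
def aif(sim_config):
    """The default synthetic plasma curve on the 300-frame axis."""
    return sim_config.plasma_curve()


@pytest.fixture(scope="session")
def ct_unidirectional(sim_config, aif):
    """Noiseless tissue curve from the unidirectional model at the truths."""
    return tissue_conc_unidirectional(aif, sim_config.truth)


@pytest.fixture(scope="session")
def ct_tofts(sim_config, aif):
    """Noiseless tissue curve from the modified Tofts model at the truths."""
    return tissue_conc_tofts(aif, sim_config.truth)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
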