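import pytest

from gvtaxon.synthetic import (SimulationConfig, simulate_taxonomy,
                               simulate_tree)


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig(seed=11)


@pytest.fixture(scope="session")
def quiet_config():
    """Noise-free, loss-free, paralog-free study system."""
    return SimulationConfig(branch_noise=0.0, marker_loss_prob=0.0,
                            paralog_prob=0.0, seed=11)


@pytest.fixture(scope="session")
def quiet_taxonomy(quiet_config):
    return simulate_taxonomy(quiet_config)


@pytest.fixture(scope="session")
def quiet_tree(quiet_taxonomy, quiet_config):
    return simulate_tree(quiet_taxonomy, quiet_config)


@pytest.fixture(scope="session")
def binary16_tree():
    """Fully resolved rooted 16-leaf tree (one genome per genus)."""
    cfg = SimulationConfig(genomes_per_genus=1, genera_per_family=2,
                           branch_noise=0.0, seed=3)
    return simulate_tree(simulate_taxonomy(cfg), cfg)
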