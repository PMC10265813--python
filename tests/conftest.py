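import numpy as np
import pytest

from plastedit.synthetic_data import SimConfig, build_plastome


@pytest.fixture(scope="session")
def default_plastome():
    """One deterministic 20-kb quadripartite plastome shared across tests."""
    cfg = SimConfig(seed=11)
    genome, genes, qmap = build_plastome(cfg)
    return cfg, genome, genes, qmap


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
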