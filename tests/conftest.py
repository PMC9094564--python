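import numpy as np
import pytest

from regvar.model import ForestParams, train
from regvar.synthetic_data import (
    SimulationConfig,
    simulate_layout,
    simulate_variants,
)

# desk-scale configuration shared across tests: 2 x 2 Mb contigs keeps every
# experiment in seconds while preserving the full genome structure
TINY_CFG = SimulationConfig(
    contig_length_bp=2_000_000,
    n_bands_per_contig=10,
    n_genes=60,
    n_regulatory_regions=200,
    n_positives=200,
    n_negative_pool=8_000,
    seed=1,
)


@pytest.fixture(scope="session")
def tiny_cfg():
    return TINY_CFG


@pytest.fixture(scope="session")
def tiny_layout(tiny_cfg):
    return simulate_layout(tiny_cfg)


@pytest.fixture(scope="session")
def tiny_sim(tiny_cfg, tiny_layout):
    return simulate_variants(tiny_cfg, tiny_layout)


@pytest.fixture(scope="session")
def tiny_model(tiny_sim):
    """Forest trained on a balanced slice of the tiny simulation."""
    rng = np.random.default_rng(7)
    pos = np.flatnonzero(tiny_sim.y == 1)
    neg = rng.choice(np.flatnonzero(tiny_sim.y == 0), size=600, replace=False)
    rows = np.concatenate([pos, np.sort(neg)])
    X, y = tiny_sim.X[rows], tiny_sim.y[rows]
    model = train(X, y, ForestParams(n_trees=60, seed=7),
                  tiny_sim.schema.names)
    return model, X, y
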