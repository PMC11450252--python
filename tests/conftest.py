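import logging

import numpy as np
import pytest

from invoffset import simdata

logging.getLogger("invoffset").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_sim():
    """Small full-range dataset shared by read-only tests."""
    cfg = simdata.SimConfig(
        n_native_pops=8, n_introduced_pops=4, n_farmed_pops=2,
        samples_per_pop=6, n_loci=300, n_adaptive_loci=20,
        fst_divergence=0.2, seed=11,
    )
    return simdata.simulate_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
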