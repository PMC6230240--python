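import numpy as np
import pytest

from cansine import simulate as sim


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_sim():
    """One small (150 kb) full simulation shared by tests that only need
    plausible multi-species data, not statistical power."""
    cfg = sim.default_config(seed=11, genome_length=150_000)
    return sim.simulate_caniform_genomes(cfg)
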