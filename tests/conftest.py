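import numpy as np
import pytest

from vnarpan import SimConfig, sample_reads, simulate_single
from vnarpan.seqio import RoundTable


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_campaign():
    """A small error-free phage campaign shared across tests."""
    cfg = SimConfig(
        n_clones=40, pool_size=5000, read_depth=1500, rounds=2,
        error_rate=0.0, seed=11,
    )
    return simulate_single(cfg, "phage")


@pytest.fixture(scope="session")
def small_reads(small_campaign):
    rng = np.random.default_rng(42)
    return sample_reads(small_campaign, 0, rng, prefix="t")


@pytest.fixture
def toy_table():
    return RoundTable(
        label="toy/R0",
        counts={"ARS": 3, "W": 1},
        rep_nt={"ARS": "GCACGTAGT", "W": "TGG"},
    )
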