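import numpy as np
import pytest

from recurcna.config import SimConfig
from recurcna.probemap import build_probe_map


@pytest.fixture(scope="session")
def small_probe_map():
    """Two chromosomes, 40 probes per arm: enough structure for segment tests."""
    return build_probe_map(n_chromosomes=2, probes_per_arm=40, arm_length_bp=30_000_000, seed=7)


@pytest.fixture(scope="session")
def small_sim_config():
    """Desk-scale config for fast cohort tests (4 chromosomes)."""
    return SimConfig(
        n_per_group={"C": 10, "L": 4, "D": 6, "LD": 4},
        n_chromosomes=4,
        probes_per_arm=60,
        empty_arms=(),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
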