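import numpy as np
import pytest

from ldphase import SimConfig, simulate_two_groups


@pytest.fixture(scope="session")
def default_panels():
    """The package-default two-group panel pair (per-chromosome lists)."""
    return simulate_two_groups(SimConfig(seed=0))


SMALL_CONFIG = SimConfig(
    seed=11,
    n_markers=240,
    n_chromosomes=2,
    chromosome_length=600_000,
    n_samples_per_group=(40, 40),
)


@pytest.fixture(scope="session")
def small_panels():
    """A quick small panel pair for IO / pipeline / invariance tests."""
    return simulate_two_groups(SMALL_CONFIG)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
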