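import numpy as np
import pytest

from chemosense import (
    CircuitParams,
    GradientProfile,
    RingGrid,
    Topology,
    screen,
)

#: symmetric reference circuit: every rate 1, both Hill constants 0.1.
#: Its IFF steady state is C* = 0.5 at any input, handy for closed-form checks.
CANONICAL = CircuitParams(k_IA=1, k_IB=1, k_CB=1, k_AC=1, l_FA=1, l_FB=1,
                          K_AC=0.1, L_BC=0.1)

SCREEN_SEED = 0
N_KEEP = 10


@pytest.fixture(scope="session")
def canonical_params():
    return CANONICAL


@pytest.fixture(scope="session")
def screened_iff():
    """First 10 IFF parameter sets passing the sensitivity/precision screen."""
    selected, _ = screen(Topology.IFF, n_samples=20_000, seed=SCREEN_SEED,
                         n_keep=N_KEEP)
    assert len(selected) == N_KEEP
    return selected


@pytest.fixture(scope="session")
def screened_nfb():
    selected, _ = screen(Topology.NFB, n_samples=20_000, seed=SCREEN_SEED,
                         n_keep=N_KEEP)
    assert len(selected) == N_KEEP
    return selected


@pytest.fixture(scope="session")
def default_profile():
    return GradientProfile()


@pytest.fixture(scope="session")
def default_grid():
    return RingGrid(20)
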