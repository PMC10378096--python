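import numpy as np
import pytest

from cothermo import fixtures as fx
from cothermo.dynamics import Distribution
from cothermo.process_model import (
    CompositeProcess,
    DependencyNetwork,
    Mechanism,
    StateSpace,
)


@pytest.fixture
def two_state():
    """One binary subsystem, rates 2 (up) and 1 (down): equilibrium (1/3, 2/3)."""
    space = StateSpace(("S",), {"S": ("0", "1")})
    mech = Mechanism(
        id="m",
        puppets=frozenset({"S"}),
        entries=(({"S": "0"}, {"S": "1"}, 2.0), ({"S": "1"}, {"S": "0"}, 1.0)),
    )
    return CompositeProcess(space, DependencyNetwork(), (mech,))


@pytest.fixture
def ring():
    return fx.biased_ring(3, 2.0, 1.0)


@pytest.fixture
def overlap():
    """Hub-and-leaves process admitting the unit structure {A, AB, AC}."""
    return fx.random_overlapping_units_process(seed=11)


def random_distribution(process: CompositeProcess, seed: int) -> Distribution:
    rng = np.random.default_rng(seed)
    return Distribution.random(process.state_space, rng)


def familywise_z(n_comparisons: int, per_test_sigma: float = 3.0) -> float:
    """Bonferroni-adjusted z threshold: k simultaneous two-sided checks with
    the same family-wise error rate as one check at ``per_test_sigma``."""
    from scipy.stats import norm

    alpha = 2.0 * norm.sf(per_test_sigma)
    return float(norm.isf(alpha / (2.0 * n_comparisons)))
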