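import numpy as np
import pytest

from evotherm import LossTable, make_landscape, make_space


@pytest.fixture
def two_state():
    """The minimal non-degenerate loss table H = {0, 1}."""
    return LossTable.from_values([0.0, 1.0])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_table(rng, n=20, lo=0.0, hi=10.0):
    return LossTable.from_values(rng.uniform(lo, hi, size=n))


@pytest.fixture
def cube_landscape():
    """8-genotype additive landscape on the L=3 binary hypercube."""
    space = make_space(3, 2)
    effects = [[0.0, 0.3], [0.0, -0.2], [0.0, 0.5]]
    return make_landscape(space, "additive", {"site_effects": effects}, seed=0)


@pytest.fixture
def two_genotype_w2():
    """L=1 binary landscape with fitness ratio w = 2 at beta = 1:
    F = {0, -log 2} so Z ratio is exactly 2."""
    space = make_space(1, 2)
    effects = [[0.0, -float(np.log(2.0))]]
    return make_landscape(space, "additive", {"site_effects": effects}, seed=0)
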