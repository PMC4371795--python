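import numpy as np
import pytest

from startleopt import CostFamily, make_cost_family


@pytest.fixture
def default_family():
    return make_cost_family()


@pytest.fixture
def quad_linear_family():
    """C_R = r^2, C_B = 1 - r on [0, 1]: closed-form minimiser r0 = p/2.

    Opportunity components are zero, so this family deliberately fails the
    audit and is used with the audit waived.
    """
    zero = lambda r: np.zeros_like(np.asarray(r, dtype=float))
    return CostFamily(
        c_r_direct=lambda r: np.square(np.asarray(r, dtype=float)),
        c_r_forgone=zero,
        c_b_direct=lambda r: 1.0 - np.asarray(r, dtype=float),
        c_b_forgone=zero,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
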