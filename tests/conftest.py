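import numpy as np
import pytest

from culturesim import ParameterSet, Population


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_params():
    """Fast scenario for smoke-level runs."""
    return ParameterSet(N=30, mu=0.1, p_w=1.0, burn_in_steps=20,
                        recorded_steps=50)


def make_population(ages, parents=None, variants=None):
    """Hand-built population for rule-level tests."""
    ages = np.asarray(ages, np.int64)
    n = ages.size
    if parents is None:
        parents = np.full(n, -1, np.int64)
    if variants is None:
        variants = np.ones((5, n), np.int64)
    return Population(ages=ages, parents=np.asarray(parents, np.int64),
                      variants=np.asarray(variants, np.int64))
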