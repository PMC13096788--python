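import numpy as np
import pytest

from nowwdist import NOWWParams


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def p_mid():
    """A well-behaved interior parameter vector used across suites."""
    return NOWWParams(1.1, 1.6, 1.8, 1.5)


def random_params(rng, n, lo=0.3, hi=3.0):
    """n random parameter vectors with all components in [lo, hi]."""
    return [NOWWParams(*rng.uniform(lo, hi, size=4)) for _ in range(n)]
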