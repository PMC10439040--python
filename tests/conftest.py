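import numpy as np
import pytest

from wienerfpt import WDMParams


@pytest.fixture
def rng():
    return np.random.default_rng(20220913)


@pytest.fixture
def base_params():
    return WDMParams(a=1.2, nu=0.5, w=0.4)


def random_params(rng, n):
    """Random parameter sets from the study prior (no variability)."""
    out = []
    for _ in range(n):
        out.append(WDMParams(a=float(rng.uniform(0.6, 2.0)),
                             nu=float(rng.standard_normal()),
                             w=float(rng.beta(8, 8))))
    return out
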