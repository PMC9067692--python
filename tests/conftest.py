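import numpy as np
import pytest

from pggsim import ParamSet


@pytest.fixture
def voluntary_params():
    """Default-parameter voluntary scenario at moderate outside payoff."""
    return ParamSet(n=20, scenario="voluntary", omega=0.925)


@pytest.fixture
def compulsory_params():
    return ParamSet(n=20, scenario="compulsory")


@pytest.fixture
def tiny_params():
    """A deliberately small population for exhaustive/oracle checks."""
    return ParamSet(
        N=4,
        n=6,
        scenario="voluntary",
        omega=0.9,
        m=0.1,
        mu=0.05,
        s=0.3,
        e=0.1,
        periods=50,
        burn_in=0,
        replicates=2,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
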