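import numpy as np
import pytest

from triscav import DimParams, EconParams, NonDimParams


@pytest.fixture
def ds39():
    """Reference dimensionless parameter set; nu1 is the usual dial."""

    def make(nu1=0.07, **overrides):
        base = dict(
            gamma=0.9, A1=0.11, A2=0.13, A3=0.4, delta=0.25,
            alpha=0.3, beta=13.0, mu=10.5, nu1=nu1, nu2=0.3,
        )
        base.update(overrides)
        return NonDimParams(**base)

    return make


@pytest.fixture
def control_params():
    """Dimensional parameters and economics of the harvesting control study."""
    p = DimParams(
        r=5.0, k=0.9, a=0.1, b=0.25, c=0.05, d=0.25, n=0.35,
        k1=0.1, k2=0.12, k3=0.48, l=0.25, m=0.2, q1=0.5, q2=0.5,
    )
    e = EconParams(
        p1=1.0, p2=1.0, C1=1.0, C2=1.0, delta1=0.05,
        nu1_econ=1.0, nu2_econ=1.0, E1max=1.0, E2max=1.0, Tf=5.0,
    )
    return p, e, np.array([5.5, 2.5, 2.5])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
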