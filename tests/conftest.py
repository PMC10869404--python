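import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")

from starbrush import (
    ChainParams,
    CoreGeometry,
    SampleMeta,
    ScatteringCurve,
    StarParams,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def simple_curve():
    """Small smooth curve with honest uncertainties."""
    q = np.linspace(0.05, 2.0, 60)
    i = 10.0 * np.exp(-(q**2))
    return ScatteringCurve(
        q=q, intensity=i, sigma=0.01 * i, meta=SampleMeta(label="fixture")
    )


@pytest.fixture
def chain_params():
    return ChainParams.from_nu(I0=100.0, N=104, nu=0.65)


@pytest.fixture
def sphere_star_params():
    return StarParams(
        Z=5.0,
        core=CoreGeometry("sphere", R=1.0),
        Rg_tail=4.0,
        beta_c=1.0,
        beta_t=1.0,
        scale=1.0,
    )
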