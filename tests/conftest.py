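import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from jpcrayleigh import (
    CensoringScheme,
    JointParams,
    JPCSample,
    PowerRayleighParams,
    generate_jpc_sample,
)

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

TRUTH1 = JointParams(PowerRayleighParams(0.5, 2.5), PowerRayleighParams(0.6, 2.69))


@pytest.fixture(scope="session")
def truth1() -> JointParams:
    """First simulation configuration (alpha1, alpha2, beta1, beta2) = (0.5, 0.6, 2.5, 2.69)."""
    return TRUTH1


@pytest.fixture(scope="session")
def scheme_3040() -> CensoringScheme:
    """Well-identified design: 30 + 30 units, 40 failures, 20 removed at the first failure."""
    return CensoringScheme(m=30, n=30, r=40, R=(20,) + (0,) * 39)


@pytest.fixture(scope="session")
def sample_3040(truth1, scheme_3040) -> JPCSample:
    return generate_jpc_sample(truth1.pop1, truth1.pop2, scheme_3040, seed=5)


@pytest.fixture(scope="session")
def toy_scheme() -> CensoringScheme:
    return CensoringScheme(m=3, n=3, r=3, R=(1, 1, 1))


@pytest.fixture(scope="session")
def toy_sample() -> JPCSample:
    """Hand-built consistent 3-failure record for direct-evaluation oracles."""
    return JPCSample(
        lam=np.array([0.4, 0.9, 1.5]),
        h=np.array([1, 0, 1]),
        s=np.array([0, 1, 0]),
        t=np.array([1, 0, 1]),
    )
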