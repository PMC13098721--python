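import numpy as np
import pytest

from smfretsim import PhysicalParams


@pytest.fixture
def params() -> PhysicalParams:
    return PhysicalParams(k_D=0.25, k_A=1.0, R0_iso=5.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
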