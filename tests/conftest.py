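import numpy as np
import pytest

from cardiogrowth.fibers import FiberFrame
from cardiogrowth.materials import MaterialParameters, scale_weights


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture(scope="session")
def cardiac_params() -> MaterialParameters:
    """Healthy-human parameter set (C0 = 0.115 kPa, B0 = 14.4, D0 = 0.001)."""
    return MaterialParameters.healthy_human()


@pytest.fixture(scope="session")
def soft_params() -> MaterialParameters:
    """Milder parameter set for fast solver tests."""
    return scale_weights(2.0, 3.0, D0=0.01)


@pytest.fixture(scope="session")
def isotropic_params() -> MaterialParameters:
    """Isotropic weight reduction (all entries of the weight matrix equal)."""
    b = 1.5
    return MaterialParameters(C0=2.0, D0=0.01, Bff=b, Bss=b, Bnn=b, Bfs=b, Bfn=b, Bsn=b)


@pytest.fixture
def axis_frame() -> FiberFrame:
    return FiberFrame.from_fiber_sheet([1.0, 0.0, 0.0], [0.0, 1.0, 0.0])
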