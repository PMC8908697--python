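import numpy as np
import pytest

from dcekin import AcquisitionProtocol, ArterialInputFunction, population_aif


@pytest.fixture(scope="session")
def protocol() -> AcquisitionProtocol:
    return AcquisitionProtocol()


@pytest.fixture(scope="session")
def frame_times(protocol) -> np.ndarray:
    return protocol.frame_times_s


@pytest.fixture(scope="session")
def aif(frame_times) -> ArterialInputFunction:
    """Default parametric plasma AIF on the dynamic frame grid."""
    return population_aif(frame_times)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260921)
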