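import numpy as np
import pytest
from hypothesis import settings

from ispgr import SequenceParams, TissueParams, get_protocol, make_phantom

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")

# The four representative tissue pairs used throughout the validation
# simulations: T1 of 500 and 1500 ms crossed with T2 of 25 and 50 ms.
VALIDATION_TISSUES = [
    TissueParams(500.0, 25.0, 1.0),
    TissueParams(500.0, 50.0, 1.0),
    TissueParams(1500.0, 25.0, 1.0),
    TissueParams(1500.0, 50.0, 1.0),
]


@pytest.fixture(scope="session")
def validation_sequence() -> SequenceParams:
    """Validation-simulation settings: TR 5 ms, FA 15 deg, 20 readouts/shot,
    t_fs 50 ms, t_bs 12 ms, t_sp 6 ms."""
    return SequenceParams(tr=5.0, alpha=15.0, k=20, t_fs=50.0, t_bs=12.0, t_sp=6.0)


@pytest.fixture(scope="session")
def invivo_protocol():
    return get_protocol("invivo_ispgr")


@pytest.fixture(scope="session")
def small_phantom():
    """Reduced-matrix single-slice 8-vial phantom for fast volume fits."""
    return make_phantom("standard_8vial", shape=(40, 40, 1))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
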