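import numpy as np
import pytest

from dcerepro import AIFModel, make_phantom, simulate_series
from dcerepro.acquisition import study_protocol


@pytest.fixture(scope="session")
def meta():
    """The 44-frame, 6-s, five-angle study protocol."""
    return study_protocol()


@pytest.fixture(scope="session")
def aif(meta):
    """Population input function with onset at the bolus frame."""
    return AIFModel(onset_time=meta.bolus_time)


@pytest.fixture(scope="session")
def phantom16():
    return make_phantom((16, 16), seed=11)


@pytest.fixture(scope="session")
def noiseless_series(phantom16, meta):
    return simulate_series(phantom16, meta, 0.0, "none", seed=11)
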