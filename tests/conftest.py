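import numpy as np
import pytest

from ctmpi import (
    AifParameters,
    TissueKinetics,
    default_config,
    generate_aif,
    tissue_curve,
)


@pytest.fixture(scope="session")
def dense_times():
    """Default 60 s acquisition grid at the internal 0.01 s step."""
    return np.arange(0.0, 60.005, 0.01)


@pytest.fixture(scope="session")
def default_aif(dense_times):
    """Noise-free dense AIF at default parameters, injection at 5 s."""
    return generate_aif(AifParameters(), dense_times, injection_start=5.0)


@pytest.fixture(scope="session")
def ideal_tac_factory(default_aif):
    """TACs in the ideal limit: complete extraction, negligible washout."""

    def make(flow_f):
        kin = TissueKinetics(flow_f=flow_f, extraction_e=1.0, dist_volume=1e6)
        return tissue_curve(default_aif, kin, baseline_hu=40.0), kin

    return make


@pytest.fixture()
def config():
    return default_config()
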