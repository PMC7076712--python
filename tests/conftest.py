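import numpy as np
import pytest

from patvis.colorimetry import load_cie_tables
from patvis.pipeline import PipelineConfig, calibrate
from patvis.synth import SynthConfig, simulate_calibration_campaign


@pytest.fixture(scope="session")
def cie_tables():
    return load_cie_tables()


@pytest.fixture(scope="session")
def calibration_campaign():
    """Default-condition calibration campaign (5 levels x 120 steady)."""
    return simulate_calibration_campaign(SynthConfig(seed=11))


@pytest.fixture(scope="session")
def fitted_model(calibration_campaign):
    """Calibration model fitted on the session campaign."""
    model, report = calibrate(calibration_campaign, PipelineConfig(seed=11))
    return model, report


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
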