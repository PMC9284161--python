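import numpy as np
import pytest

from conescale import (
    DryingPath,
    ScaleActuationModel,
    default_scale_model,
    preset_curve,
)


@pytest.fixture(scope="session")
def scale():
    """Default measured geometry (dry-state cross-sections)."""
    return default_scale_model()


@pytest.fixture(scope="session")
def drying_path():
    """Drying path with the reported endpoints (70 wet, 1170 dry MPa)."""
    return DryingPath()


@pytest.fixture(scope="session")
def sclerenchyma_sim():
    return preset_curve("sclerenchyma_sim")


@pytest.fixture(scope="session")
def actuation_model():
    return ScaleActuationModel()


@pytest.fixture(scope="session")
def calibrated(actuation_model):
    """Results of the dry-state calibration (target 24.4 deg)."""
    return actuation_model.fit()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
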