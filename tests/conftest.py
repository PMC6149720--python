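import numpy as np
import pytest

from sandlam.models import BilayerModel, ContrastSpec, InstrumentConfig, VolumetricInputs

PAPER_CONTRAST_FRACTIONS = (0.08, 0.20, 0.50)


@pytest.fixture(scope="session")
def default_model() -> BilayerModel:
    return BilayerModel()


@pytest.fixture(scope="session")
def contrasts():
    return [ContrastSpec.from_d2o_fraction(f) for f in PAPER_CONTRAST_FRACTIONS]


@pytest.fixture(scope="session")
def instrument() -> InstrumentConfig:
    return InstrumentConfig()


@pytest.fixture(scope="session")
def volumetrics() -> VolumetricInputs:
    return VolumetricInputs()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260924)
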