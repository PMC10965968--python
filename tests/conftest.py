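import numpy as np
import pytest

from snarephys.polymer import DumbbellConfig, ThermalContext, WLCParams


@pytest.fixture(scope="session")
def th() -> ThermalContext:
    return ThermalContext()  # 296 K, kBT ~ 4.087 pN nm


@pytest.fixture(scope="session")
def cfg() -> DumbbellConfig:
    return DumbbellConfig()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def dna() -> WLCParams:
    return WLCParams(persistence_length=50.0, contour_length=770.0, stretch_modulus=1000.0)


@pytest.fixture(scope="session")
def peptide() -> WLCParams:
    return WLCParams(persistence_length=0.6, contour_length=20.0)
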