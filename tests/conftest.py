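import numpy as np
import pytest

from sononeedle import load_default_model
from sononeedle.ultrasound_sim import NeedleGeometry, ProbeConfig, ScenePhantom


@pytest.fixture(scope="session")
def model():
    """The shipped calibration (fitted to the quasi-free SR table)."""
    return load_default_model()


@pytest.fixture(scope="session")
def probe():
    return ProbeConfig()


@pytest.fixture(scope="session")
def geometry():
    return NeedleGeometry()


@pytest.fixture(scope="session")
def scene():
    return ScenePhantom()


@pytest.fixture(scope="session")
def scene_noiseless():
    return ScenePhantom(background_scatterer_density=0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
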