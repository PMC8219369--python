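import numpy as np
import pytest
from hypothesis import settings

from szloop import detect, synthgen

settings.register_profile("ci", derandomize=True)
settings.load_profile("ci")

FS = 512.0
TRAIN_SEED = 100


@pytest.fixture(scope="session")
def detector_config():
    return detect.DetectorConfig()


@pytest.fixture(scope="session")
def background_model():
    return synthgen.BackgroundModel()


@pytest.fixture(scope="session")
def seizure_model():
    return synthgen.SeizureModel()


@pytest.fixture(scope="session")
def training_recording(background_model, seizure_model):
    """Two hours of epileptic LFP used to build the seizure library."""
    return synthgen.generate_epileptic_recording(
        2 * 3600.0, FS, background_model, seizure_model, seed=TRAIN_SEED
    )


@pytest.fixture(scope="session")
def library(training_recording, detector_config):
    rec, truth = training_recording
    return synthgen.build_library(rec, truth, detector_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
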