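import numpy as np
import pytest

from spatialspeech.beamform import design_beamformer
from spatialspeech.core import default_bte_array
from spatialspeech.doa import train_default_model
from spatialspeech.posteriorgram import PhonemeInventory, train_default_provider


@pytest.fixture(scope="session")
def geometry():
    return default_bte_array()


@pytest.fixture(scope="session")
def doa_model(geometry):
    """Localizer trained once on the standard synthetic recipe (19 sectors,
    diffuse noise, SNRs -15/0/+15 dB, 2 s per scene)."""
    return train_default_model(geometry, seed=0, duration_s=2.0)


@pytest.fixture(scope="session")
def provider():
    """Phoneme classifier trained once on 60 s of multi-condition streams."""
    return train_default_provider(seed=0, train_duration_s=60.0)


@pytest.fixture(scope="session")
def bank(geometry):
    return design_beamformer(geometry)


@pytest.fixture(scope="session")
def inventory():
    return PhonemeInventory()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
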