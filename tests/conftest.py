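import numpy as np
import pytest

from oprars.audiograms import Audiogram, synth_audiogram
from oprars.prescription import ChannelBank, baseline_prescription
from oprars.workbench import generate_tokens


@pytest.fixture(scope="session")
def bank():
    return ChannelBank()


@pytest.fixture
def flat40():
    """Flat 40 dB HL loss at all 11 frequencies."""
    return Audiogram(thresholds_db_hl=np.full(11, 40.0), label="flat40")


@pytest.fixture
def normal_hearing():
    return Audiogram(thresholds_db_hl=np.zeros(11), label="normal")


@pytest.fixture(scope="session")
def moderate_audiogram():
    return synth_audiogram(5, seed=11)


@pytest.fixture(scope="session")
def small_tokens():
    """A small token set shared across the suite (8 tokens, 16 kHz)."""
    return generate_tokens(8, seed=3)


@pytest.fixture
def flat40_baseline(flat40, bank):
    return baseline_prescription(flat40, bank)
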