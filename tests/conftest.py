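import numpy as np
import pytest

from binoflick import ModelParams
from binoflick.synth import REFERENCE_PARAMS


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def pupil_params() -> ModelParams:
    """Group-median pupillometry parameter set (strong suppression)."""
    return REFERENCE_PARAMS["pupil"]


@pytest.fixture
def eeg1f_params() -> ModelParams:
    """Group-median first-harmonic EEG parameter set (weak suppression)."""
    return REFERENCE_PARAMS["eeg_1f"]


@pytest.fixture
def matching_params() -> ModelParams:
    """Group-median matching observer (matching mode, no Rmax)."""
    return REFERENCE_PARAMS["matching"]
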