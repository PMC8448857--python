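import numpy as np
import pandas as pd
import pytest

from entraineeg.montage import CHANNELS_8
from entraineeg.preprocess import EpochSet
from entraineeg.synth import OscillatorModel


@pytest.fixture
def model():
    return OscillatorModel()


@pytest.fixture
def rhythmic_active_trial():
    return pd.Series(
        {
            "block": 0, "trial": 0, "rhythmicity": "rhythmic",
            "stimulation": "active", "target_side": "left",
            "p1": 105.0, "p2": 205.0, "p3": 305.0, "p4": 405.0,
        }
    )


@pytest.fixture
def sham_trial(rhythmic_active_trial):
    trial = rhythmic_active_trial.copy()
    trial["stimulation"] = "sham"
    return trial


def make_sinusoid_epochs(
    freq=10.0, amp=1.0, phases=(0.0,), fs=100.0, span=(-300.0, 900.0),
    ch_names=("O2",), dc=0.0,
):
    """EpochSet of pure sinusoid trials, one per phase offset (radians)."""
    n = int(round((span[1] - span[0]) * fs / 1000.0))
    t = span[0] + np.arange(n) * (1000.0 / fs)
    data = np.stack(
        [
            np.tile(amp * np.cos(2 * np.pi * freq * t / 1000.0 + ph) + dc,
                    (len(ch_names), 1))
            for ph in phases
        ]
    )
    return EpochSet(data, t, fs, tuple(ch_names))


@pytest.fixture
def sinusoid_epochs():
    return make_sinusoid_epochs


def rhythmic_trials(n):
    """Schedule-like frame of n identical rhythmic-active trials."""
    return pd.DataFrame(
        {
            "block": 0, "trial": np.arange(n), "rhythmicity": "rhythmic",
            "stimulation": "active", "target_side": "left",
            "p1": 105.0, "p2": 205.0, "p3": 305.0, "p4": 405.0,
        }
    )


@pytest.fixture
def reduced_montage():
    return CHANNELS_8
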