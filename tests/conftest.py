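from __future__ import annotations

import numpy as np
import pytest

from cereb_band_psd.core import STRUCTURES, BehaviorSchedule, Episode, RecordingSession
from cereb_band_psd.synthetic import default_duration_params, reduced_design

#: Reduced-scale episode-length medians shared by calibration fixtures.
REDUCED_MEDIANS = {
    "resting": 7.0,
    "grooming": 4.0,
    "locomotion": 4.5,
    "rearing": 4.0,
    "sniffing": 4.0,
}


def null_reduced_design(seed: int, **overrides):
    """Reduced design with every injected effect removed (g=1, kappa=0,
    no duration shifts, no rat intercept), for calibration runs."""
    base = dict(
        seed=seed,
        band_gain={},
        duration_coupling={},
        rat_sd=0.0,
        duration_params=default_duration_params(
            medians=REDUCED_MEDIANS, log_sd=0.45, w1_shifts={}
        ),
    )
    base.update(overrides)
    return reduced_design(**base)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def white_session(rng):
    """Hand-built 60 s session: three white-noise channels at 1 kHz with a
    fixed schedule.  Bypasses the generator entirely."""
    fs = 1000.0
    n = 60_000
    channels = {s: rng.normal(0, 1.0, n) for s in STRUCTURES}
    schedule = BehaviorSchedule(
        [
            Episode("resting", 0.0, 12.0),
            Episode("grooming", 13.0, 16.0),
            Episode("locomotion", 17.0, 24.0),
            Episode("rearing", 25.0, 31.0),
            Episode("sniffing", 32.0, 41.0),
            Episode("resting", 41.0, 59.5),
        ]
    )
    return RecordingSession(
        rat_id="T01", group="control", week=1, fs=fs, channels=channels, episodes=schedule
    )
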