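"""Shared fixtures: small synthetic recordings and cohorts.

Everything is generated at test time from fixed seeds; no data files.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from cardioresp.synthetic import SimConfig, generate_recording
from cardioresp.types import EventSpec


@pytest.fixture(scope="session")
def quiet_recording():
    """5 minutes of quiet breathing (no events), default noise."""
    return generate_recording(SimConfig(record_length_s=300.0, seed=11))


@pytest.fixture(scope="session")
def noiseless_recording():
    """5 minutes, no events, no channel noise, no RR jitter."""
    cfg = SimConfig(
        record_length_s=300.0, seed=12, rr_jitter_ms=0.0,
        noise_sd={"ecg": 0.0, "airflow": 0.0, "ribcage": 0.0, "abdomen": 0.0},
    )
    return generate_recording(cfg)


@pytest.fixture(scope="session")
def event_recording():
    """10 minutes containing one event of each kind."""
    events = [
        EventSpec("hypopnea", 100.0, 20.0),
        EventSpec("obstructive_apnea", 250.0, 20.0),
        EventSpec("central_apnea", 400.0, 20.0),
    ]
    return generate_recording(SimConfig(record_length_s=600.0, event_list=events, seed=13))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(autouse=True)
def _quiet_warnings():
    """Feature extraction on degenerate windows warns by design."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        yield
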