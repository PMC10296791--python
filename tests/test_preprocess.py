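"""Filter frequency responses and segmentation arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import signal as sps

from cardioresp.preprocess import filter_airflow, filter_ecg, segmentize
from cardioresp.synthetic import SimConfig, generate_recording
from cardioresp.types import EventSpec


def _filtfilt_gain(cutoff, order, fs, freq):
    """Magnitude response of the zero-phase (squared) Butterworth."""
    sos = sps.butter(order, cutoff, btype="low", fs=fs, output="sos")
    _, h = sps.sosfreqz(sos, worN=[freq], fs=fs)
    return np.abs(h[0]) ** 2


def test_airflow_filter_dc_gain_is_unity():
    x = np.full(800, 3.7)
    y = filter_airflow(x, fs=8.0)
    np.testing.assert_allclose(y, x, rtol=1e-6)


def test_airflow_filter_attenuates_1hz_as_designed():
    """Steady-state rejection of a 1-Hz tone matches the squared
    Butterworth magnitude response (edge transients excluded)."""
    fs = 8.0
    t = np.arange(0, 600, 1 / fs)
    x = np.sin(2 * np.pi * 1.0 * t)
    y = filter_airflow(x, fs)
    inner = slice(int(60 * fs), -int(60 * fs))
    measured = np.sqrt(np.mean(y[inner] ** 2)) / np.sqrt(np.mean(x[inner] ** 2))
    expected = _filtfilt_gain(0.3, 4, fs, 1.0)
    assert measured < 0.05
    assert measured == pytest.approx(expected, rel=0.10)


def test_airflow_filter_keeps_slow_component():
    fs = 8.0
    t = np.arange(0, 300, 1 / fs)
    slow = np.sin(2 * np.pi * 0.05 * t)
    x = slow + np.sin(2 * np.pi * 2.0 * t)
    y = filter_airflow(x, fs)
    r = np.corrcoef(y, slow)[0, 1]
    assert r > 0.99


def test_airflow_filter_idempotent_on_band_limited_signal():
    fs = 8.0
    t = np.arange(0, 120, 1 / fs)
    x = np.sin(2 * np.pi * 0.05 * t)
    once = filter_airflow(x, fs)
    twice = filter_airflow(once, fs)
    inner = slice(int(10 * fs), -int(10 * fs))
    np.testing.assert_allclose(twice[inner], once[inner], atol=5e-3)


def test_airflow_filter_rejects_unsatisfiable_rate():
    with pytest.raises(ValueError, match="cannot support"):
        filter_airflow(np.zeros(100), fs=0.5)


def test_ecg_filter_removes_ramp():
    fs = 128.0
    x = np.linspace(0, 5, int(10 * fs))
    y = filter_ecg(x, fs)
    inner = y[int(fs):-int(fs)]
    assert np.max(np.abs(inner)) < 0.05


def test_ecg_filter_preserves_impulses():
    """QRS-like impulses on a flat baseline survive baseline subtraction;
    oracle: the cascaded median of an isolated impulse train is ~0."""
    fs = 128.0
    x = np.zeros(int(20 * fs))
    locs = np.arange(64, len(x) - 64, int(fs))
    x[locs] = 1.0
    y = filter_ecg(x, fs)
    assert np.all(np.abs(y[locs] - 1.0) < 0.05)


def test_ecg_filter_zero_in_zero_out():
    y = filter_ecg(np.zeros(2000), 128.0)
    np.testing.assert_array_equal(y, 0.0)


def test_ecg_filter_window_longer_than_signal():
    with pytest.raises(ValueError, match="median window"):
        filter_ecg(np.zeros(10), 128.0)


def _recording_of_length(seconds, events=()):
    return generate_recording(
        SimConfig(record_length_s=seconds, event_list=list(events), seed=1)
    )


def test_segment_counts_no_overlap():
    rec = _recording_of_length(60.0)
    assert len(segmentize(rec, 10.0, 0.0)) == 6


def test_segment_counts_90_percent_overlap():
    rec = _recording_of_length(60.0)
    assert len(segmentize(rec, 10.0, 0.9)) == 51


def test_majority_overlap_labeling():
    rec = _recording_of_length(60.0, [EventSpec("central_apnea", 30.0, 20.0)])
    labels = [s.label for s in segmentize(rec, 10.0, 0.0)]
    assert labels == ["normal"] * 3 + ["central_apnea"] * 2 + ["normal"]


@settings(derandomize=True, max_examples=60, deadline=None)
@given(
    length=st.integers(min_value=20, max_value=600),
    window=st.sampled_from([5.0, 10.0, 20.0]),
    overlap=st.sampled_from([0.0, 0.5, 0.8, 0.9]),
)
def test_segment_count_formula(length, window, overlap):
    """Window count equals the brute-force enumeration of admissible starts."""
    from cardioresp.types import Recording

    rec = Recording(channels={"airflow": np.zeros(int(length * 8))}, fs={"airflow": 8.0})
    segs = segmentize(rec, window, overlap, channels=["airflow"])
    step = window * (1 - overlap)
    expected = 0
    k = 0
    while k * step + window <= length + 1e-9:
        expected += 1
        k += 1
    assert len(segs) == expected
    assert all(abs(s.start_s - i * step) < 1e-9 for i, s in enumerate(segs))
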