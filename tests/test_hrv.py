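"""R-peak detection accuracy and HRV feature definitions."""

import numpy as np
import pytest

from cardioresp.hrv import detect_r_peaks, freq_domain, poincare, time_domain
from cardioresp.preprocess import filter_ecg
from cardioresp.synthetic import SimConfig, generate_recording
from cardioresp.types import RRSeries


def rr_from_intervals(rr_ms):
    """Build an RRSeries whose interval list is exactly ``rr_ms``."""
    rr_ms = np.asarray(rr_ms, dtype=float)
    times = np.concatenate([[0.0], np.cumsum(rr_ms / 1000.0)])
    return RRSeries(times, rr_ms)


def _match_stats(detected_idx, truth_idx, tol=3):
    tp = sum(1 for t in truth_idx if np.min(np.abs(detected_idx - t)) <= tol)
    fp = sum(1 for d in detected_idx if np.min(np.abs(truth_idx - d)) > tol)
    return tp / len(truth_idx), (len(detected_idx) - fp) / len(detected_idx)


def test_r_peaks_noiseless_exact(noiseless_recording):
    rec = noiseless_recording
    ecg = filter_ecg(rec.channels["ecg"], rec.fs["ecg"])
    rr = detect_r_peaks(ecg, rec.fs["ecg"])
    det = np.round(rr.r_times_s * rec.fs["ecg"]).astype(int)
    sens, ppv = _match_stats(det, rec.true_r_peaks, tol=3)
    assert sens == 1.0
    assert ppv == 1.0


def test_r_peaks_with_noise_snr20():
    rec = generate_recording(SimConfig(record_length_s=120.0, seed=31,
                                       noise_sd={"ecg": 0.0}))
    ecg = rec.channels["ecg"]
    rng = np.random.default_rng(0)
    snr = 10 ** (20 / 10)
    noise_sd = np.sqrt(np.mean(ecg**2) / snr)
    noisy = ecg + rng.normal(0, noise_sd, len(ecg))
    rr = detect_r_peaks(filter_ecg(noisy, 128.0), 128.0)
    det = np.round(rr.r_times_s * 128.0).astype(int)
    sens, ppv = _match_stats(det, rec.true_r_peaks, tol=5)
    assert sens >= 0.99
    assert ppv >= 0.99


def test_r_peaks_flat_signal_empty_with_warning():
    with pytest.warns(UserWarning):
        rr = detect_r_peaks(np.zeros(128 * 10), 128.0)
    assert len(rr) == 0


def test_nn50_pnn50_use_total_interval_denominator():
    td = time_domain(rr_from_intervals([800, 860, 865, 920]))
    assert td["nn50"] == 2  # |60| > 50 and |55| > 50
    assert td["pnn50"] == pytest.approx(2 / 4)  # denominator = 4 intervals


def test_constant_rr_degenerates_cleanly():
    td = time_domain(rr_from_intervals([800] * 10))
    assert td["nn50"] == 0
    assert td["rmsd_ms"] == 0
    assert td["mad_ms"] == 0
    assert td["cvrr"] == 0
    assert np.isnan(td["serial_corr_lag1"])


def test_rmsd_single_difference():
    td = time_domain(rr_from_intervals([800, 900]))
    assert td["rmsd_ms"] == pytest.approx(100.0)


def test_too_few_intervals_all_nan():
    td = time_domain(rr_from_intervals([800]))
    assert all(np.isnan(v) for v in td.values())


def test_freq_domain_hf_modulation():
    """A 0.25-Hz RR modulation concentrates power in the HF band."""
    t = np.arange(0, 120, 0.8)
    rr_ms = 800 + 50 * np.sin(2 * np.pi * 0.25 * t[1:])
    rr = RRSeries(t, rr_ms)
    fd = freq_domain(rr)
    assert fd["hf"] / fd["tp"] > 0.8


def test_freq_domain_constant_rr_zero_power():
    fd = freq_domain(rr_from_intervals([800] * 100))
    assert fd["tp"] < 1e-10


def test_normalized_powers_sum_to_one(rng):
    rr = rr_from_intervals(800 + 40 * rng.standard_normal(150))
    fd = freq_domain(rr)
    assert fd["lf_norm"] + fd["hf_norm"] == pytest.approx(1.0, abs=1e-9)


def test_poincare_constant_series():
    sd1, sd2, _ = poincare(rr_from_intervals([800] * 6))
    assert sd1 == 0 and sd2 == 0


def test_poincare_alternating_series():
    sd1, sd2, ratio = poincare(rr_from_intervals([800, 900, 800, 900]))
    diffs = np.array([100.0, -100.0, 100.0])
    assert sd1 == pytest.approx(np.sqrt(np.var(diffs, ddof=1) / 2))
    assert sd2 == pytest.approx(0.0)
    assert np.isnan(ratio)


def test_poincare_matches_geometric_projection(rng):
    """Closed forms equal SDs of projections on y=x and its perpendicular."""
    for _ in range(50):
        x = 800 + 60 * rng.standard_normal(rng.integers(10, 200))
        rr = rr_from_intervals(np.abs(x) + 200)
        sd1, sd2, _ = poincare(rr)
        a, b = rr.rr_ms[:-1], rr.rr_ms[1:]
        along = (a + b) / np.sqrt(2)
        perp = (b - a) / np.sqrt(2)
        assert sd1 == pytest.approx(np.std(perp, ddof=1))
        assert sd2 == pytest.approx(np.std(along, ddof=1))


def test_poincare_rotation_identity(rng):
    rr = rr_from_intervals(800 + 50 * rng.standard_normal(100))
    sd1, sd2, _ = poincare(rr)
    a, b = rr.rr_ms[:-1], rr.rr_ms[1:]
    assert sd1**2 + sd2**2 == pytest.approx(np.var(a, ddof=1) + np.var(b, ddof=1),
                                            rel=1e-9)
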