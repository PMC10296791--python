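"""EDR extraction and cardiopulmonary-coupling spectrum."""

import numpy as np
import pytest

from cardioresp.cpc import cpc_spectrum, extract_edr, resample_4hz
from cardioresp.types import RRSeries


def _triangle_ecg(fs=128.0, n_beats=5, rr_s=1.0, rise=0.04, amp=1.0):
    """Isoceles-triangle QRS train: rising slope +amp/rise, falling -amp/rise."""
    n = int((n_beats + 1) * rr_s * fs)
    x = np.zeros(n)
    t = np.arange(n) / fs
    beats = (np.arange(n_beats) + 1) * rr_s
    for tb in beats:
        m = np.abs(t - tb) <= rise
        x[m] = amp * (1 - np.abs(t[m] - tb) / rise)
    return x, beats


def test_edr_triangle_slope_range_is_2s():
    fs, rise, amp = 128.0, 0.04, 1.0
    x, beats = _triangle_ecg(fs, rise=rise, amp=amp)
    rr = RRSeries.from_times(beats)
    edr = extract_edr(x, fs, rr)
    s = amp / rise
    # central differencing rounds the triangle's corners slightly
    np.testing.assert_allclose(edr.slope_range, 2 * s, rtol=0.05)


def test_edr_scales_linearly_with_amplitude():
    fs = 128.0
    x, beats = _triangle_ecg(fs)
    rr = RRSeries.from_times(beats)
    base = extract_edr(x, fs, rr).slope_range
    scaled = extract_edr(3.5 * x, fs, rr).slope_range
    np.testing.assert_allclose(scaled, 3.5 * base, rtol=1e-9)


def test_edr_edge_beat_omitted():
    fs = 128.0
    x = np.zeros(int(4 * fs))
    rr = RRSeries.from_times([3 / fs, 1.0, 2.0, 3.0])
    edr = extract_edr(x, fs, rr)
    assert edr.n_dropped == 1
    assert len(edr.times_s) == 3


def test_edr_matches_per_beat_brute_force(rng):
    fs = 128.0
    x = rng.standard_normal(int(30 * fs))
    beats = np.arange(1.0, 29.0, 0.8)
    rr = RRSeries.from_times(beats)
    edr = extract_edr(x, fs, rr)
    deriv = np.gradient(x) * fs
    half = int(round(0.05 * fs))
    expected = []
    for t in beats:
        i = int(round(t * fs))
        w = deriv[i - half: i + half + 1]
        expected.append(w.max() - w.min())
    np.testing.assert_allclose(edr.slope_range, expected, rtol=1e-12)


def test_resample_recovers_slow_sinusoid(rng):
    """Spline error on a 0.2-Hz modulation stays within the fourth-order
    interpolation bound for physiological beat spacings (boundary knots,
    where the not-a-knot spline is only cubic-exact, excluded)."""
    t_beats = np.cumsum(rng.uniform(0.7, 1.0, size=150))
    values = np.sin(2 * np.pi * 0.2 * t_beats)
    grid, out = resample_4hz(t_beats, values)
    truth = np.sin(2 * np.pi * 0.2 * grid)
    inner = (grid > t_beats[0] + 3.0) & (grid < t_beats[-1] - 3.0)
    assert np.max(np.abs(out[inner] - truth[inner])) < 0.01


def test_resample_constant_and_no_extrapolation():
    t = np.array([0.0, 1.0, 2.0, 3.0])
    grid, out = resample_4hz(t, np.full(4, 2.5))
    np.testing.assert_allclose(out, 2.5)
    assert grid[0] >= t[0] and grid[-1] <= t[-1] + 1e-9


def test_resample_rejects_non_monotone_times():
    with pytest.raises(ValueError, match="increasing"):
        resample_4hz([0.0, 2.0, 1.0, 3.0], [1, 2, 3, 4])


def test_cpc_self_coherence_equals_cross_power_squared(rng):
    x = rng.standard_normal(1024)
    spec = cpc_spectrum(x, x)
    from scipy import signal as sps
    f, sxx = sps.welch(x - x.mean(), fs=4.0, nperseg=128)
    nz = sxx > 1e-12 * sxx.max()
    np.testing.assert_allclose(spec.cpc[nz], np.abs(sxx[nz]) ** 2, rtol=1e-6)


def test_cpc_independent_noise_much_below_coupled(rng):
    x = rng.standard_normal(4096)
    y = rng.standard_normal(4096)
    coupled = cpc_spectrum(x, x)
    indep = cpc_spectrum(x, y)
    assert np.median(indep.cpc) < 0.05 * np.median(coupled.cpc)


def test_cpc_peak_at_shared_frequency(rng):
    t = np.arange(2048) / 4.0
    shared = np.sin(2 * np.pi * 0.25 * t)
    x = shared + 0.1 * rng.standard_normal(len(t))
    y = 0.8 * shared + 0.1 * rng.standard_normal(len(t))
    spec = cpc_spectrum(x, y)
    peak = spec.freqs_hz[np.argmax(spec.cpc)]
    df = spec.freqs_hz[1] - spec.freqs_hz[0]
    assert abs(peak - 0.25) <= df


def test_cpc_offset_invariance_and_nonnegativity(rng):
    x = rng.standard_normal(512)
    y = rng.standard_normal(512)
    a = cpc_spectrum(x, y)
    b = cpc_spectrum(x + 100.0, y - 7.0)
    np.testing.assert_allclose(a.cpc, b.cpc, atol=1e-9)
    assert np.all(a.cpc >= 0)


def test_cpc_zero_variance_warns_zero_spectrum():
    with pytest.warns(UserWarning):
        spec = cpc_spectrum(np.ones(128), np.arange(128.0))
    assert np.all(spec.cpc == 0)
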