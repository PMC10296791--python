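"""ECG-derived respiration and the cardiopulmonary-coupling spectrum.

The respiratory surrogate (EDR) is the per-beat QRS slope range: the
difference between the maximum and minimum of the ECG first derivative in
a symmetric 100-ms window centred on each R wave. Both the RR tachogram
and the EDR beat series are cubic-spline resampled to 4 Hz, and their
coupling spectrum is

    CPC(w) = C_xy(w) * |S_xy(w)|^2

with C_xy the coherence coefficient (square root of the magnitude-squared
coherence) and S_xy the cross power spectrum. A classical variant
C_xy(w)^2 * |S_xy(w)| is available behind ``variant="coh2_cross"``.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import interpolate, signal

from .types import CPCSpectrum, EDRSeries, RRSeries

__all__ = ["extract_edr", "resample_4hz", "cpc_spectrum", "cpc_features"]

#: CPC band edges in Hz (low-frequency and high-frequency coupling).
CPC_LF = (0.01, 0.1)
CPC_HF = (0.1, 0.4)


def extract_edr(
    ecg: np.ndarray, fs: float, r_peaks: RRSeries, window_ms: float = 100.0
) -> EDRSeries:
    """Per-beat QRS slope range from the ECG first derivative.

    Beats whose +-window/2 neighbourhood is clipped by a record edge are
    omitted; the count of dropped beats is reported on the result.
    """
    ecg = np.asarray(ecg, dtype=float)
    if len(r_peaks) == 0:
        raise ValueError("r_peaks is empty")
    deriv = np.gradient(ecg) * fs
    half = int(round(window_ms / 2000.0 * fs))
    times, values = [], []
    dropped = 0
    for t in r_peaks.r_times_s:
        idx = int(round(t * fs))
        lo, hi = idx - half, idx + half + 1
        if lo < 0 or hi > len(ecg):
            dropped += 1
            continue
        w = deriv[lo:hi]
        values.append(float(np.max(w) - np.min(w)))
        times.append(float(t))
    return EDRSeries(np.asarray(times), np.asarray(values), n_dropped=dropped)


def resample_4hz(
    times_s: np.ndarray, values: np.ndarray, fs_out: float = 4.0
) -> tuple[np.ndarray, np.ndarray]:
    """Cubic-spline a beat-indexed series onto a uniform grid.

    The grid spans [first, last] beat time only (no extrapolation).
    """
    times_s = np.asarray(times_s, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(times_s) < 4:
        raise ValueError("need >= 4 beats for cubic-spline resampling")
    if np.any(np.diff(times_s) <= 0):
        raise ValueError("beat times must be strictly increasing")
    spline = interpolate.CubicSpline(times_s, values)
    grid = np.arange(times_s[0], times_s[-1] + 1e-12, 1.0 / fs_out)
    return grid, spline(grid)


def cpc_spectrum(
    rr4: np.ndarray,
    edr4: np.ndarray,
    fs: float = 4.0,
    nperseg: int = 128,
    variant: str = "coh_cross2",
) -> CPCSpectrum:
    """Cardiopulmonary-coupling spectrum of two 4-Hz series.

    ``variant="coh_cross2"`` is C * |S|^2 (the printed composition);
    ``variant="coh2_cross"`` is C^2 * |S|. Inputs are mean-removed, so the
    result is invariant to additive offsets.
    """
    rr4 = np.asarray(rr4, dtype=float)
    edr4 = np.asarray(edr4, dtype=float)
    if len(rr4) != len(edr4):
        raise ValueError("series must have equal length")
    if len(rr4) < 64:
        raise ValueError("need >= 64 samples for the coupling spectrum")
    if variant not in ("coh_cross2", "coh2_cross"):
        raise ValueError(f"unknown CPC variant: {variant!r}")

    x = rr4 - np.mean(rr4)
    y = edr4 - np.mean(edr4)
    if np.allclose(x, 0) or np.allclose(y, 0):
        warnings.warn("zero-variance input; CPC spectrum is all zero")
        f = np.fft.rfftfreq(nperseg, 1.0 / fs)
        z = np.zeros_like(f)
        return CPCSpectrum(f, z, 0.0, 0.0, np.nan)

    nps = min(nperseg, len(x))
    f, sxy = signal.csd(x, y, fs=fs, nperseg=nps)
    _, msc = signal.coherence(x, y, fs=fs, nperseg=nps)
    coh = np.sqrt(np.clip(msc, 0.0, 1.0))
    cross = np.abs(sxy)
    cpc = coh * cross ** 2 if variant == "coh_cross2" else coh ** 2 * cross

    df = f[1] - f[0]
    lf_mask = (f >= CPC_LF[0]) & (f < CPC_LF[1])
    hf_mask = (f >= CPC_HF[0]) & (f < CPC_HF[1])
    lf = float(np.sum(cpc[lf_mask]) * df)
    hf = float(np.sum(cpc[hf_mask]) * df)
    ratio = lf / hf if hf > 0 else np.nan
    return CPCSpectrum(f, cpc, lf, hf, ratio)


def cpc_features(
    rr: RRSeries, edr: EDRSeries, fs_interp: float = 4.0, **kwargs
) -> dict[str, float]:
    """CPC band features for one analysis window; NaN when too short."""
    out = {"cpc_lf": np.nan, "cpc_hf": np.nan, "cpc_lf_hf": np.nan}
    if len(rr.rr_ms) < 4 or len(edr.times_s) < 4:
        return out
    try:
        grid_r, rr4 = resample_4hz(rr.r_times_s[1:], rr.rr_ms, fs_interp)
        grid_e, edr4 = resample_4hz(edr.times_s, edr.slope_range, fs_interp)
    except ValueError:
        return out
    n = min(len(rr4), len(edr4))
    if n < 64:
        return out
    spec = cpc_spectrum(rr4[:n], edr4[:n], fs=fs_interp, **kwargs)
    out["cpc_lf"] = spec.lf_power
    out["cpc_hf"] = spec.hf_power
    out["cpc_lf_hf"] = spec.lf_hf_ratio
    return out
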