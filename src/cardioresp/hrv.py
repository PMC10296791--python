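"""R-peak detection and heart-rate-variability features.

R peaks are found with the Pan-Tompkins cascade (band-pass, derivative,
squaring, moving-window integration, adaptive dual thresholds with
search-back and a 200-ms refractory period). Time-domain, frequency-domain
and Poincare features follow the standard HRV definitions, with two
deliberate conventions:

* pNN50 uses the *total RR-interval count* as its denominator (not the
  number of successive differences);
* the triangular index uses a histogram bin width of 1/128 s, the tick of
  a 128-Hz ECG clock.

Features that are undefined on a given series (zero variance, too few
beats) are returned as NaN rather than raising.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import interpolate, signal

from .types import RRSeries

__all__ = [
    "detect_r_peaks",
    "time_domain",
    "freq_domain",
    "poincare",
    "hrv_features",
    "TIME_DOMAIN_FEATURES",
    "FREQ_DOMAIN_FEATURES",
]

TIME_DOMAIN_FEATURES = (
    "serial_corr_lag1", "serial_corr_lag2", "serial_corr_lag3",
    "nn50", "pnn50", "rmsd_ms", "mad_ms", "cvrr", "tri_index",
)
FREQ_DOMAIN_FEATURES = ("tp", "vlf", "lf", "hf", "lf_norm", "hf_norm", "lf_hf")

#: (low, high) band edges in Hz; bands are half-open [low, high).
BANDS = {"vlf": (0.0033, 0.04), "lf": (0.04, 0.15), "hf": (0.15, 0.4)}
TP_BAND = (0.0, 0.4)


# ---------------------------------------------------------------------------
# Pan-Tompkins
# ---------------------------------------------------------------------------

def detect_r_peaks(ecg: np.ndarray, fs: float, refractory_s: float = 0.2) -> RRSeries:
    """Detect R peaks with the Pan-Tompkins algorithm.

    Returns an empty :class:`RRSeries` (with a warning) when no peaks are
    found. The returned times are refined to the local maximum of the
    band-passed ECG, so they line up with the R wave rather than with the
    integration-window peak.
    """
    ecg = np.asarray(ecg, dtype=float)
    if fs < 100:
        raise ValueError("detect_r_peaks requires fs >= 100 Hz")
    if len(ecg) < 2 * fs:
        raise ValueError("signal shorter than 2 s")
    if np.ptp(ecg) == 0:
        warnings.warn("flat ECG signal; no R peaks")
        return RRSeries(np.empty(0), np.empty(0))

    sos = signal.butter(3, (5.0, 15.0), btype="band", fs=fs, output="sos")
    bp = signal.sosfiltfilt(sos, ecg)
    deriv = np.gradient(bp) * fs
    sq = deriv ** 2
    win = max(int(round(0.150 * fs)), 1)
    mwi = np.convolve(sq, np.ones(win) / win, mode="same")

    min_dist = max(int(round(refractory_s * fs)), 1)
    cand, _ = signal.find_peaks(mwi, distance=min_dist)
    if len(cand) == 0:
        warnings.warn("no candidate peaks in integrated signal")
        return RRSeries(np.empty(0), np.empty(0))

    # Adaptive dual thresholds on the MWI peak heights (classic recursions).
    spki = float(np.max(mwi[cand[: max(1, len(cand) // 10)]]))
    npki = float(np.mean(mwi[: int(2 * fs)]))
    accepted: list[int] = []
    rr_history: list[float] = []

    def threshold1() -> float:
        return npki + 0.25 * (spki - npki)

    i = 0
    while i < len(cand):
        idx = cand[i]
        height = mwi[idx]
        if height > threshold1():
            if accepted and (idx - accepted[-1]) < min_dist:
                if height > mwi[accepted[-1]]:
                    accepted[-1] = idx
            else:
                if accepted:
                    rr_history.append((idx - accepted[-1]) / fs)
                accepted.append(idx)
            spki = 0.125 * height + 0.875 * spki
        else:
            # search-back: if the expected beat is overdue, re-examine the
            # interval with the halved threshold
            if accepted and rr_history:
                mean_rr = float(np.mean(rr_history[-8:]))
                if (idx - accepted[-1]) / fs > 1.66 * mean_rr and height > 0.5 * threshold1():
                    rr_history.append((idx - accepted[-1]) / fs)
                    accepted.append(idx)
                    spki = 0.25 * height + 0.75 * spki
                else:
                    npki = 0.125 * height + 0.875 * npki
            else:
                npki = 0.125 * height + 0.875 * npki
        i += 1

    if not accepted:
        warnings.warn("no peaks exceeded the adaptive threshold")
        return RRSeries(np.empty(0), np.empty(0))

    # refine to the band-passed R wave within half an integration window
    half = max(int(round(0.075 * fs)), 1)
    refined = []
    for idx in accepted:
        lo, hi = max(idx - half, 0), min(idx + half + 1, len(bp))
        refined.append(lo + int(np.argmax(bp[lo:hi])))
    refined = np.unique(refined)
    # enforce refractory after refinement
    keep = [refined[0]]
    for idx in refined[1:]:
        if idx - keep[-1] >= min_dist:
            keep.append(idx)
        elif bp[idx] > bp[keep[-1]]:
            keep[-1] = idx
    r_idx = np.asarray(keep)
    return RRSeries.from_times(r_idx / fs)


# ---------------------------------------------------------------------------
# time domain
# ---------------------------------------------------------------------------

def _serial_corr(rr: np.ndarray, lag: int) -> float:
    if len(rr) <= lag + 1:
        return np.nan
    a, b = rr[:-lag], rr[lag:]
    if np.std(a) == 0 or np.std(b) == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def time_domain(
    rr: RRSeries, lags: tuple[int, ...] = (1, 2, 3), tri_bin_s: float = 1.0 / 128
) -> dict[str, float]:
    """Time-domain HRV features; NaN where undefined."""
    out = {k: np.nan for k in TIME_DOMAIN_FEATURES}
    x = rr.rr_ms
    if len(x) < 2:
        return out
    d = np.diff(x)
    out["nn50"] = float(np.sum(np.abs(d) > 50.0))
    out["pnn50"] = out["nn50"] / len(x)  # denominator: total RR count
    out["rmsd_ms"] = float(np.sqrt(np.mean(d ** 2)))
    out["mad_ms"] = float(np.mean(np.abs(x - np.mean(x))))
    out["cvrr"] = float(np.std(x, ddof=1) / np.mean(x))
    bin_ms = tri_bin_s * 1000.0
    edges = np.arange(np.min(x), np.max(x) + 2 * bin_ms, bin_ms)
    counts, _ = np.histogram(x, bins=edges)
    out["tri_index"] = len(x) / float(np.max(counts))
    for lag in lags:
        out[f"serial_corr_lag{lag}"] = _serial_corr(x, lag)
    return out


# ---------------------------------------------------------------------------
# frequency domain
# ---------------------------------------------------------------------------

def resample_tachogram(
    rr: RRSeries, fs_out: float = 4.0
) -> tuple[np.ndarray, np.ndarray]:
    """Cubic-spline the tachogram (RR value at each beat end) onto a
    uniform grid. Returns (times, rr_ms)."""
    if len(rr.rr_ms) < 4:
        raise ValueError("need >= 4 RR intervals for spline resampling")
    t_beat = rr.r_times_s[1:]
    spline = interpolate.CubicSpline(t_beat, rr.rr_ms)
    grid = np.arange(t_beat[0], t_beat[-1] + 1e-12, 1.0 / fs_out)
    return grid, spline(grid)


def freq_domain(
    rr: RRSeries,
    fs_interp: float = 4.0,
    nperseg: int = 256,
) -> dict[str, float]:
    """Welch band powers of the spline-resampled, mean-removed tachogram.

    Band powers are bin sums (power spectral density x bin width) over
    half-open bands, so VLF + LF + HF = TP exactly whenever the grid has no
    bin below the VLF edge.
    """
    out = {k: np.nan for k in FREQ_DOMAIN_FEATURES}
    try:
        _, tach = resample_tachogram(rr, fs_interp)
    except ValueError:
        return out
    if len(tach) < 8:
        return out
    x = tach - np.mean(tach)
    if np.allclose(x, 0):
        out.update(tp=0.0, vlf=0.0, lf=0.0, hf=0.0)
        return out
    f, psd = signal.welch(x, fs=fs_interp, nperseg=min(nperseg, len(x)))
    df = f[1] - f[0]

    def band_power(lo: float, hi: float) -> float:
        mask = (f >= lo) & (f < hi) if lo > 0 else (f > 0) & (f < hi)
        return float(np.sum(psd[mask]) * df)

    out["vlf"] = band_power(*BANDS["vlf"])
    out["lf"] = band_power(*BANDS["lf"])
    out["hf"] = band_power(*BANDS["hf"])
    out["tp"] = band_power(*TP_BAND)
    denom = out["tp"] - out["vlf"]
    if denom > 0:
        out["lf_norm"] = out["lf"] / denom
        out["hf_norm"] = out["hf"] / denom
    out["lf_hf"] = out["lf"] / out["hf"] if out["hf"] > 0 else np.nan
    return out


# ---------------------------------------------------------------------------
# Poincare
# ---------------------------------------------------------------------------

def poincare(rr: RRSeries) -> tuple[float, float, float]:
    """SD1/SD2 of the lag-1 Poincare plot via the rotation closed forms.

    SD1 is the spread perpendicular to the identity line, SD2 the spread
    along it: sd1 = sqrt(var(diff)/2), sd2 = sqrt(var(sum)/2).
    """
    x = rr.rr_ms
    if len(x) < 3:
        return np.nan, np.nan, np.nan
    a, b = x[:-1], x[1:]
    sd1 = float(np.sqrt(np.var(b - a, ddof=1) / 2.0))
    sd2 = float(np.sqrt(np.var(b + a, ddof=1) / 2.0))
    ratio = sd1 / sd2 if sd2 > 0 else np.nan
    return sd1, sd2, ratio


def hrv_features(rr: RRSeries) -> dict[str, float]:
    """All HRV features (time, frequency, Poincare) as one flat mapping."""
    out = time_domain(rr)
    out.update(freq_domain(rr))
    sd1, sd2, ratio = poincare(rr)
    out.update(sd1_ms=sd1, sd2_ms=sd2, sd1_sd2=ratio)
    return out
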