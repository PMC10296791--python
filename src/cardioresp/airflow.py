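"""Breath detection and morphological airflow features.

Breaths are segmented by zero crossings of the mean-removed, low-pass
filtered flow: a positive half-wave is an inspiration, the following
negative half-wave the matching expiration. Half-waves shorter than 0.5 s
or with a peak below 5 % of the reference amplitude are treated as noise
and merged into their neighbours. Per-breath features follow the standard
morphological definitions:

* respiratory frequency RF = 1 / cycle (breaths per second),
* inspiratory duty cycle IDC = inspiratory time / cycle,
* slope = inspiratory volume / inspiratory time,

with "volumes" the time integrals of |flow| over each phase (arbitrary
amplitude x seconds; no volumetric calibration) and areas the signed
integrals of flow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import Segment

__all__ = [
    "Breath",
    "detect_breaths",
    "breath_features",
    "segment_airflow_features",
    "AIRFLOW_FEATURES",
]

AIRFLOW_FEATURES = ("rf", "idc", "insp_vol", "exp_vol", "insp_area", "total_area", "slope")


@dataclass
class Breath:
    """One inspiration/expiration cycle with its integrals."""

    insp_start_s: float
    insp_end_s: float
    exp_end_s: float
    insp_volume: float
    exp_volume: float
    insp_area: float
    total_area: float

    def __post_init__(self) -> None:
        if not self.insp_start_s < self.insp_end_s < self.exp_end_s:
            raise ValueError("breath phases must be ordered insp_start < insp_end < exp_end")

    @property
    def cycle_s(self) -> float:
        return self.exp_end_s - self.insp_start_s

    @property
    def insp_time_s(self) -> float:
        return self.insp_end_s - self.insp_start_s


def _half_waves(x: np.ndarray, min_len: int, min_peak: float) -> list[tuple[int, int, int]]:
    """(start, end, sign) runs of one sign, with short/small runs merged
    into the preceding run."""
    sign = np.where(x >= 0, 1, -1)
    # raw runs
    change = np.flatnonzero(np.diff(sign)) + 1
    bounds = np.concatenate([[0], change, [len(x)]])
    runs = [(int(bounds[i]), int(bounds[i + 1]), int(sign[bounds[i]]))
            for i in range(len(bounds) - 1)]
    # merge noise runs into the previous one
    merged: list[tuple[int, int, int]] = []
    for start, end, s in runs:
        peak = float(np.max(np.abs(x[start:end])))
        keep = (end - start) >= min_len and peak >= min_peak
        if merged and (not keep or merged[-1][2] == s):
            p_start, p_end, p_sign = merged[-1]
            merged[-1] = (p_start, end, p_sign)
        elif keep:
            merged.append((start, end, s))
    return merged


def detect_breaths(
    flow: np.ndarray,
    fs: float,
    min_duration_s: float = 0.5,
    min_peak: float | None = None,
    min_peak_frac: float = 0.05,
) -> list[Breath]:
    """Segment filtered airflow into breaths.

    ``min_peak`` is the absolute amplitude below which a half-wave is
    treated as noise; when None it defaults to ``min_peak_frac`` of the
    signal's own maximum amplitude. Pass a record-level reference when
    analysing short windows so that a fully apneic window (noise only)
    yields *no* breaths instead of noise-breaths.
    """
    flow = np.asarray(flow, dtype=float)
    if len(flow) < 3 or np.ptp(flow) == 0:
        return []
    x = flow - np.mean(flow)
    if min_peak is None:
        min_peak = min_peak_frac * float(np.max(np.abs(x)))
    min_len = max(int(round(min_duration_s * fs)), 1)

    waves = _half_waves(x, min_len, min_peak)
    breaths = []
    t = np.arange(len(x)) / fs
    for (s0, e0, sg0), (s1, e1, sg1) in zip(waves, waves[1:]):
        if sg0 != 1 or sg1 != -1:
            continue
        insp = x[s0:e0]
        exp = x[s1:e1]
        if np.max(np.abs(insp)) < min_peak or np.max(np.abs(exp)) < min_peak:
            continue
        insp_vol = float(np.trapezoid(np.abs(insp), dx=1.0 / fs))
        exp_vol = float(np.trapezoid(np.abs(exp), dx=1.0 / fs))
        insp_area = float(np.trapezoid(insp, dx=1.0 / fs))
        total_area = float(np.trapezoid(x[s0:e1], dx=1.0 / fs))
        breaths.append(
            Breath(
                insp_start_s=t[s0], insp_end_s=t[s1], exp_end_s=t[e1 - 1] + 1.0 / fs,
                insp_volume=insp_vol, exp_volume=exp_vol,
                insp_area=insp_area, total_area=total_area,
            )
        )
    return breaths


def breath_features(b: Breath) -> dict[str, float]:
    """Morphological features of one breath; NaN-flagged if degenerate."""
    if b.insp_time_s <= 0:
        return {k: np.nan for k in AIRFLOW_FEATURES}
    return {
        "rf": 1.0 / b.cycle_s,
        "idc": b.insp_time_s / b.cycle_s,
        "insp_vol": b.insp_volume,
        "exp_vol": b.exp_volume,
        "insp_area": b.insp_area,
        "total_area": b.total_area,
        "slope": b.insp_volume / b.insp_time_s,
    }


def segment_airflow_features(
    seg: Segment, min_peak: float | None = None
) -> dict[str, float]:
    """Mean per-breath features over breaths starting inside the segment.

    A window with no detected breath — the apnea signature — falls back to
    all-zero features (RF 0, volumes 0).
    """
    flow = seg.channels["airflow"]
    fs = seg.fs["airflow"]
    breaths = detect_breaths(flow, fs, min_peak=min_peak)
    if not breaths:
        return {k: 0.0 for k in AIRFLOW_FEATURES}
    feats = [breath_features(b) for b in breaths]
    return {k: float(np.nanmean([f[k] for f in feats])) for k in AIRFLOW_FEATURES}
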