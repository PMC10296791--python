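"""Per-segment feature-table extraction.

Ties the signal modules together: filter the channels once per record,
detect R peaks and extract the EDR once per record, then compute airflow
morphology, HRV time/frequency/Poincare features, the six entropies and
the cardiopulmonary-coupling band powers for every 10-s segment. Because
10 s holds only a dozen beats, beat-based features use a context window
(segment +- 25 s by default) centred on the segment; the feature row is
still labelled by the segment itself.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from . import airflow as airflow_mod
from . import cpc as cpc_mod
from . import entropy as entropy_mod
from . import hrv as hrv_mod
from . import preprocess
from .types import EDRSeries, Recording, RRSeries

__all__ = ["extract_features", "extract_feature_table", "FEATURE_COLUMNS", "META_COLUMNS"]

META_COLUMNS = ("subject", "start_s", "label", "kind")

FEATURE_COLUMNS = (
    airflow_mod.AIRFLOW_FEATURES
    + hrv_mod.TIME_DOMAIN_FEATURES
    + hrv_mod.FREQ_DOMAIN_FEATURES
    + ("sd1_ms", "sd2_ms", "sd1_sd2")
    + ("shannon_en", "renyi_en", "tsallis_en", "transfer_en", "hvg_degree_en", "alphabet_en")
    + ("cpc_lf", "cpc_hf", "cpc_lf_hf")
)


def _beats_in_window(rr: RRSeries, lo: float, hi: float) -> RRSeries:
    mask = (rr.r_times_s >= lo) & (rr.r_times_s < hi)
    times = rr.r_times_s[mask]
    if len(times) < 2:
        return RRSeries(times, np.empty(0))
    return RRSeries.from_times(times)


def _edr_in_window(edr: EDRSeries, lo: float, hi: float) -> EDRSeries:
    mask = (edr.times_s >= lo) & (edr.times_s < hi)
    return EDRSeries(edr.times_s[mask], edr.slope_range[mask])


def extract_features(
    rec: Recording,
    window_s: float = 10.0,
    overlap_frac: float = 0.0,
    context_s: float = 25.0,
    entropy_cfg: entropy_mod.EntropyConfig | None = None,
) -> pd.DataFrame:
    """Feature table of one recording (one row per segment).

    ``context_s`` widens the beat-based analyses symmetrically around each
    segment; set it to 0 to analyse strictly within the window.
    """
    rec.require(("ecg", "airflow"), stage="feature extraction")
    entropy_cfg = entropy_cfg or entropy_mod.EntropyConfig()

    flow = preprocess.filter_airflow(rec.channels["airflow"], rec.fs["airflow"])
    ecg = preprocess.filter_ecg(rec.channels["ecg"], rec.fs["ecg"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rr = hrv_mod.detect_r_peaks(ecg, rec.fs["ecg"])
        edr = (
            cpc_mod.extract_edr(ecg, rec.fs["ecg"], rr)
            if len(rr) > 0
            else EDRSeries(np.empty(0), np.empty(0))
        )

    # record-level amplitude reference so apneic windows yield no breaths
    flow_ref = 0.05 * float(np.max(np.abs(flow - np.mean(flow))))

    filtered = Recording(
        channels={**rec.channels, "airflow": flow},
        fs=dict(rec.fs),
        annotations=list(rec.annotations),
        subject_id=rec.subject_id,
    )
    segments = preprocess.segmentize(
        filtered, window_s=window_s, overlap_frac=overlap_frac,
        channels=["airflow"],
    )

    rows = []
    duration = rec.duration_s
    for seg in segments:
        row: dict[str, float] = {
            "subject": rec.subject_id,
            "start_s": seg.start_s,
            "label": seg.three_class,
            "kind": seg.label,
        }
        row.update(airflow_mod.segment_airflow_features(seg, min_peak=flow_ref))

        lo = max(seg.start_s - context_s, 0.0)
        hi = min(seg.end_s + context_s, duration)
        rr_win = _beats_in_window(rr, lo, hi)
        edr_win = _edr_in_window(edr, lo, hi)
        row.update(hrv_mod.hrv_features(rr_win))
        edr_aligned = None
        if len(edr_win.times_s) >= 2 and len(rr_win.rr_ms) >= 1:
            # pair rr[i] with the EDR value at the beat opening interval i
            lookup = dict(zip(edr_win.times_s, edr_win.slope_range))
            vals = [lookup.get(t, np.nan) for t in rr_win.r_times_s[:-1]]
            edr_aligned = np.asarray(vals)
            if np.any(np.isnan(edr_aligned)):
                edr_aligned = None
        row.update(entropy_mod.entropy_features(rr_win.rr_ms, edr_aligned, entropy_cfg))
        row.update(cpc_mod.cpc_features(rr_win, edr_win))
        rows.append(row)

    df = pd.DataFrame(rows, columns=list(META_COLUMNS) + list(FEATURE_COLUMNS))
    return df


def extract_feature_table(recordings: list[Recording], **kwargs) -> pd.DataFrame:
    """Concatenated feature table of a cohort."""
    tables = [extract_features(rec, **kwargs) for rec in recordings]
    return pd.concat(tables, ignore_index=True)
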