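"""Event aggregation, apnea-hypopnea index and severity grading.

Per-segment predictions are merged into events (maximal runs of abnormal
segments; majority type, ties to apnea; runs shorter than the 10-s
clinical minimum discarded) and counted per recording hour:

    AHI = events / hours,

graded none (AHI < 5), mild (5 <= AHI < 15), moderate (15 <= AHI < 30),
severe (AHI >= 30). The denominator is total recording time, not sleep
time (no sleep staging in this pipeline), which biases AHI slightly
downward relative to a staged montage.
"""

from __future__ import annotations

import numpy as np

from .models import EvalReport, evaluate
from .types import AHIReport, EventSpec, MIN_EVENT_DURATION_S

__all__ = ["segments_to_events", "compute_ahi", "severity_of", "screen_cohort"]

SEVERITY_THRESHOLDS = ((30.0, "severe"), (15.0, "moderate"), (5.0, "mild"))

_ABNORMAL = {"H", "A"}


def severity_of(ahi: float) -> str:
    """Map an AHI value onto the half-open clinical severity bands."""
    if ahi < 0:
        raise ValueError("AHI cannot be negative")
    for lo, name in SEVERITY_THRESHOLDS:
        if ahi >= lo:
            return name
    return "none"


def _per_second_labels(labels, window_s: float, overlap_frac: float) -> list[str]:
    """Reduce (possibly overlapping) window labels to per-second majority."""
    step = window_s * (1 - overlap_frac)
    total = int(np.ceil((len(labels) - 1) * step + window_s))
    votes: list[dict[str, int]] = [dict() for _ in range(total)]
    for k, lab in enumerate(labels):
        lo = int(np.floor(k * step))
        hi = int(np.ceil(k * step + window_s))
        for s in range(lo, min(hi, total)):
            votes[s][lab] = votes[s].get(lab, 0) + 1
    out = []
    for v in votes:
        if not v:
            out.append("N")
            continue
        best = max(v.values())
        winners = sorted(lab for lab, n in v.items() if n == best)
        # tie goes to the abnormal label, A before H
        out.append("A" if "A" in winners else ("H" if "H" in winners else winners[0]))
    return out


def segments_to_events(
    labels,
    window_s: float = 10.0,
    overlap_frac: float = 0.0,
    start_s: float = 0.0,
) -> list[EventSpec]:
    """Merge time-ordered per-segment class labels (N/H/A) into events.

    Maximal runs of abnormal labels become one event of the majority type
    (tie -> apnea); events shorter than the 10-s minimum are discarded.
    Overlapping-window predictions are first reduced to per-second
    majority labels.
    """
    labels = list(labels)
    if not labels:
        return []
    if overlap_frac > 0:
        per = _per_second_labels(labels, window_s, overlap_frac)
        unit = 1.0
    else:
        per = labels
        unit = window_s

    events: list[EventSpec] = []
    run_start = None
    run_labels: list[str] = []

    def close_run(end_idx: int) -> None:
        nonlocal run_start, run_labels
        if run_start is None:
            return
        duration = (end_idx - run_start) * unit
        if duration >= MIN_EVENT_DURATION_S:
            n_a = sum(1 for l in run_labels if l == "A")
            n_h = len(run_labels) - n_a
            kind = "apnea" if n_a >= n_h else "hypopnea"
            events.append(EventSpec(
                kind=kind, onset_s=start_s + run_start * unit, duration_s=duration
            ))
        run_start, run_labels = None, []

    for i, lab in enumerate(per):
        if lab in _ABNORMAL:
            if run_start is None:
                run_start = i
            run_labels.append(lab)
        else:
            close_run(i)
    close_run(len(per))
    return events


def compute_ahi(events: list[EventSpec], recording_hours: float) -> AHIReport:
    """AHI and severity for one recording."""
    if recording_hours <= 0:
        raise ValueError("recording_hours must be > 0")
    per_type: dict[str, int] = {}
    for ev in events:
        per_type[ev.kind] = per_type.get(ev.kind, 0) + 1
    ahi = len(events) / recording_hours
    return AHIReport(
        n_events=len(events), hours=recording_hours, ahi=ahi,
        severity=severity_of(ahi), per_type=per_type,
    )


def screen_cohort(
    predicted_ahi,
    true_ahi,
    threshold: float = 5.0,
) -> EvalReport:
    """Dichotomize predicted and true AHI at a clinical threshold and
    score the resulting subject-level screening decision."""
    pred = (np.asarray(predicted_ahi, dtype=float) >= threshold).astype(int)
    true = (np.asarray(true_ahi, dtype=float) >= threshold).astype(int)
    if len(pred) != len(true):
        raise ValueError("predicted and true AHI lists must align")
    return evaluate(true, pred, classes=[0, 1])
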