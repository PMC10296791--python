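"""Shared domain containers for the respiratory-event pipeline.

All timestamps are seconds from record start (float); annotation intervals
are half-open ``[onset, onset + duration)``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

#: Event vocabulary. ``apnea`` is the aggregate type produced when
#: three-class predictions (N/H/A) are merged into events before the
#: obstructive/central subtype stage has run.
EVENT_KINDS = (
    "normal",
    "hypopnea",
    "apnea",
    "obstructive_apnea",
    "central_apnea",
    "mixed",
)

APNEA_KINDS = ("apnea", "obstructive_apnea", "central_apnea", "mixed")
ABNORMAL_KINDS = ("hypopnea",) + APNEA_KINDS

#: Minimum clinically scoreable event duration in seconds.
MIN_EVENT_DURATION_S = 10.0

#: Three-class label used by the segment classifier.
THREE_CLASS = ("N", "H", "A")


def kind_to_class(kind: str) -> str:
    """Map an event kind to the three-class label N/H/A."""
    if kind == "normal":
        return "N"
    if kind == "hypopnea":
        return "H"
    if kind in APNEA_KINDS:
        return "A"
    raise ValueError(f"unknown event kind: {kind!r}")


@dataclass(frozen=True)
class EventSpec:
    """A single annotated respiratory event.

    Parameters
    ----------
    kind : str
        One of :data:`EVENT_KINDS`.
    onset_s, duration_s : float
        Event start and length in seconds; the event occupies the
        half-open interval ``[onset_s, onset_s + duration_s)``.
    """

    kind: str
    onset_s: float
    duration_s: float

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind: {self.kind!r}")
        if self.onset_s < 0:
            raise ValueError(f"onset_s must be >= 0, got {self.onset_s}")
        if self.duration_s <= 0:
            raise ValueError(f"duration_s must be > 0, got {self.duration_s}")
        if self.kind in ABNORMAL_KINDS and self.duration_s < MIN_EVENT_DURATION_S:
            raise ValueError(
                f"{self.kind} events must last >= {MIN_EVENT_DURATION_S:g} s, "
                f"got {self.duration_s:g} s"
            )

    @property
    def end_s(self) -> float:
        return self.onset_s + self.duration_s


def check_non_overlapping(events: list[EventSpec]) -> list[EventSpec]:
    """Return events sorted by onset; raise naming the first overlapping pair."""
    ordered = sorted(events, key=lambda e: e.onset_s)
    for a, b in zip(ordered, ordered[1:]):
        if b.onset_s < a.end_s:
            raise ValueError(
                f"overlapping events: {a.kind} [{a.onset_s:g}, {a.end_s:g}) and "
                f"{b.kind} [{b.onset_s:g}, {b.end_s:g})"
            )
    return ordered


@dataclass
class Recording:
    """Multichannel recording with per-channel sampling rates.

    ``channels`` maps canonical names (``ecg``, ``airflow``, ``ribcage``,
    ``abdomen``; others are carried but ignored downstream) to 1-D sample
    arrays; ``fs`` maps each channel to its sampling rate in Hz.
    ``true_r_peaks`` holds ground-truth R-peak sample indices (at the ECG
    rate) and exists only for synthetic recordings.
    """

    channels: dict[str, np.ndarray]
    fs: dict[str, float]
    annotations: list[EventSpec] = field(default_factory=list)
    true_r_peaks: Optional[np.ndarray] = None
    subject_id: str = "S0"

    def __post_init__(self) -> None:
        for name in self.channels:
            if name not in self.fs:
                raise ValueError(f"channel {name!r} has no sampling rate")
            self.channels[name] = np.asarray(self.channels[name], dtype=float)
        self.annotations = check_non_overlapping(list(self.annotations))

    @property
    def duration_s(self) -> float:
        durations = [len(x) / self.fs[c] for c, x in self.channels.items()]
        return max(durations) if durations else 0.0

    def require(self, names: tuple[str, ...] | list[str], stage: str) -> None:
        """Raise if any of ``names`` is missing, naming the pipeline stage."""
        missing = [n for n in names if n not in self.channels]
        if missing:
            raise KeyError(
                f"pipeline stage {stage!r} requires channel(s) "
                f"{', '.join(repr(m) for m in missing)} not present in recording"
            )


@dataclass
class Segment:
    """A fixed-length analysis window cut from a recording."""

    channels: dict[str, np.ndarray]
    fs: dict[str, float]
    start_s: float
    length_s: float
    label: str = "normal"  # event kind covering > 50 % of the window

    @property
    def end_s(self) -> float:
        return self.start_s + self.length_s

    @property
    def three_class(self) -> str:
        return kind_to_class(self.label)


@dataclass
class RRSeries:
    """R-peak times (s) and successive RR intervals (ms)."""

    r_times_s: np.ndarray
    rr_ms: np.ndarray

    def __post_init__(self) -> None:
        self.r_times_s = np.asarray(self.r_times_s, dtype=float)
        self.rr_ms = np.asarray(self.rr_ms, dtype=float)
        if len(self.r_times_s) >= 2 and np.any(np.diff(self.r_times_s) <= 0):
            raise ValueError("r_times_s must be strictly increasing")
        if len(self.rr_ms) != max(len(self.r_times_s) - 1, 0):
            raise ValueError("len(rr_ms) must equal len(r_times_s) - 1")
        if np.any(self.rr_ms <= 0):
            raise ValueError("all rr_ms must be > 0")

    @classmethod
    def from_times(cls, r_times_s: np.ndarray) -> "RRSeries":
        r = np.asarray(r_times_s, dtype=float)
        return cls(r, np.diff(r) * 1000.0)

    def __len__(self) -> int:
        return len(self.r_times_s)


@dataclass
class EDRSeries:
    """Per-beat ECG-derived respiration (QRS slope range, units/s)."""

    times_s: np.ndarray
    slope_range: np.ndarray
    n_dropped: int = 0  # beats whose window was clipped by a record edge

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.slope_range = np.asarray(self.slope_range, dtype=float)
        if len(self.times_s) != len(self.slope_range):
            raise ValueError("times_s and slope_range must align")


@dataclass
class CPCSpectrum:
    """Cardiopulmonary-coupling spectrum and its band summaries."""

    freqs_hz: np.ndarray
    cpc: np.ndarray
    lf_power: float
    hf_power: float
    lf_hf_ratio: float


@dataclass
class FusionSeries:
    """Nearest-state-point distance series from a two-lead trajectory."""

    d: np.ndarray
    source: str = "ribcage+abdomen"
    normalization: str = "none"  # {"none", "zscore"}

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        if np.any(self.d < 0):
            raise ValueError("fusion distances must be >= 0")

    def __len__(self) -> int:
        return len(self.d)


@dataclass
class AHIReport:
    """Apnea-hypopnea index summary for one recording."""

    n_events: int
    hours: float
    ahi: float
    severity: str
    per_type: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class SplitSpec:
    """Train/test split protocol."""

    mode: str = "stratified_random"  # or "by_subject"
    test_frac: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("stratified_random", "by_subject"):
            raise ValueError(f"unknown split mode: {self.mode!r}")
        if not 0 < self.test_frac < 1:
            raise ValueError("test_frac must be in (0, 1)")
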