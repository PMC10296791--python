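"""Annotated synthetic polysomnography generator.

Produces multichannel recordings (ECG at 128 Hz; oronasal airflow, ribcage
and abdomen effort at 8 Hz) carrying the statistical signatures that the
respiratory-event pipeline exploits:

* ECG built from a Gaussian P-QRS-T template placed at R-times driven by an
  RR process with respiratory sinus arrhythmia (RSA) and an event-locked
  cyclic variation (bradycardia during the event, rebound tachycardia after),
  plus respiratory amplitude modulation of the QRS so that an ECG-derived
  respiration (EDR) surrogate is recoverable.
* Breath-shaped airflow with an asymmetric cycle (inspiration occupying 40 %
  of the period) whose envelope collapses to <= 10 % of baseline during
  apnea and to an intermediate level during hypopnea.
* Thoracoabdominal effort that persists during obstructive apnea (with
  paradoxical rib/abdomen phase opposition) but vanishes during central
  apnea.

Amplitude transitions are ramped in the 0.5 s *outside* each annotated
window so that the in-window envelope contracts hold exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .types import (
    APNEA_KINDS,
    EventSpec,
    Recording,
    check_non_overlapping,
)

__all__ = ["SimConfig", "generate_recording", "generate_cohort", "make_event_list"]

# (center offset from R in s, amplitude, width in s) for P, Q, R, S, T
ECG_TEMPLATE = (
    (-0.20, 0.15, 0.025),
    (-0.025, -0.10, 0.010),
    (0.0, 1.00, 0.012),
    (0.025, -0.15, 0.010),
    (0.30, 0.30, 0.050),
)

_DEFAULT_NOISE = {"ecg": 0.01, "airflow": 0.02, "ribcage": 0.02, "abdomen": 0.02}


@dataclass
class SimConfig:
    """Parameters of one synthetic overnight (or shorter) recording.

    Amplitude factors are relative to the quiet-breathing baseline of each
    channel. The event-locked RR modulation (``apnea_rr_gain``) and the
    hypopnea airflow depth are free simulator parameters, not claims about
    physiology; defaults are chosen to be typical of polysomnography.
    """

    record_length_s: float = 300.0
    ecg_fs: float = 128.0
    resp_fs: float = 8.0
    mean_hr_bpm: float = 70.0
    breath_rate_hz: float = 0.25  # 15 breaths/min
    rsa_gain: float = 0.04  # fractional RR modulation at breath rate
    rr_jitter_ms: float = 10.0  # white beat-to-beat RR jitter (SD)
    edr_gain: float = 0.15  # respiratory QRS amplitude modulation
    insp_frac: float = 0.40  # inspiration fraction of the breath cycle
    apnea_rr_gain: float = 0.10  # RR lengthens by this during apnea ...
    post_event_s: float = 15.0  # ... and shortens by it for this long after
    hypopnea_depth: float = 0.5  # airflow envelope during hypopnea
    apnea_floor: float = 0.015  # airflow envelope during apnea
    oa_effort_level: float = 0.7  # effort envelope during obstructive apnea
    ca_effort_floor: float = 0.05  # effort envelope during central apnea
    hypopnea_effort_level: float = 0.7
    event_list: list[EventSpec] = field(default_factory=list)
    noise_sd: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_NOISE))
    seed: int = 0

    def validate(self) -> None:
        if self.record_length_s <= 0:
            raise ValueError("record_length_s must be > 0")
        if self.resp_fs < 2 * self.breath_rate_hz:
            raise ValueError("resp_fs must satisfy Nyquist for the breath rate")
        if self.ecg_fs < 100:
            raise ValueError("ecg_fs too low for the QRS template")
        for ev in self.event_list:
            if ev.end_s > self.record_length_s:
                raise ValueError(
                    f"event {ev.kind} ending at {ev.end_s:g} s exceeds record "
                    f"length {self.record_length_s:g} s"
                )
        check_non_overlapping(self.event_list)


def _event_rr_factor(t: float, events: list[EventSpec], cfg: SimConfig) -> float:
    """Multiplicative RR modulation at time ``t`` from the event schedule."""
    for ev in events:
        if ev.kind == "normal":
            continue
        gain = cfg.apnea_rr_gain if ev.kind in APNEA_KINDS else cfg.apnea_rr_gain / 2
        if ev.onset_s <= t < ev.end_s:
            return 1.0 + gain
        if ev.end_s <= t < ev.end_s + cfg.post_event_s:
            return 1.0 - gain
    return 1.0


def _beat_times(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Integrate the RR process into a strictly increasing beat-time train."""
    rr0 = 60.0 / cfg.mean_hr_bpm
    times = []
    t = rr0 * rng.uniform(0.2, 0.8) if cfg.rr_jitter_ms > 0 else rr0 / 2
    while t < cfg.record_length_s:
        times.append(t)
        rr = rr0 * (
            1.0
            + cfg.rsa_gain * np.sin(2 * np.pi * cfg.breath_rate_hz * t)
        )
        rr *= _event_rr_factor(t, cfg.event_list, cfg)
        rr += rng.normal(0.0, cfg.rr_jitter_ms / 1000.0) if cfg.rr_jitter_ms > 0 else 0.0
        t += max(rr, 0.25)  # refractory floor
    return np.asarray(times)


def _breath_phase_wave(phase: np.ndarray, insp_frac: float) -> np.ndarray:
    """Asymmetric breath shape on cycle phase in [0, 1).

    Inspiration is a positive half-sine over ``insp_frac`` of the cycle;
    expiration a negative half-sine over the remainder, with its amplitude
    scaled so inspired and expired "volumes" balance.
    """
    frac = np.mod(phase, 1.0)
    wave = np.where(
        frac < insp_frac,
        np.sin(np.pi * frac / insp_frac),
        -(insp_frac / (1 - insp_frac)) * np.sin(np.pi * (frac - insp_frac) / (1 - insp_frac)),
    )
    return wave


def _envelope(t: np.ndarray, events: list[EventSpec], level_of, ramp_s: float = 0.5) -> np.ndarray:
    """Piecewise envelope: 1 at baseline, ``level_of(event)`` inside each
    event window, with linear ramps placed in the ``ramp_s`` seconds outside
    the window so the in-window level is exact."""
    env = np.ones_like(t)
    for ev in events:
        lvl = level_of(ev)
        if lvl is None:
            continue
        down = (t >= ev.onset_s - ramp_s) & (t < ev.onset_s)
        env[down] = np.minimum(env[down], 1 + (lvl - 1) * (t[down] - (ev.onset_s - ramp_s)) / ramp_s)
        inside = (t >= ev.onset_s) & (t < ev.end_s)
        env[inside] = lvl
        up = (t >= ev.end_s) & (t < ev.end_s + ramp_s)
        env[up] = np.minimum(env[up], lvl + (1 - lvl) * (t[up] - ev.end_s) / ramp_s)
    return env


def _ecg_signal(
    cfg: SimConfig, beats: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    n = int(round(cfg.record_length_s * cfg.ecg_fs))
    ecg = np.zeros(n)
    t_axis = np.arange(n) / cfg.ecg_fs
    half_sup = 0.45  # template support around each R, seconds
    for tb in beats:
        lo = max(int((tb - half_sup) * cfg.ecg_fs), 0)
        hi = min(int((tb + half_sup) * cfg.ecg_fs) + 1, n)
        if hi <= lo:
            continue
        tt = t_axis[lo:hi] - tb
        # respiration modulates QRS amplitude -> EDR is recoverable
        qrs_scale = 1.0 + cfg.edr_gain * np.sin(2 * np.pi * cfg.breath_rate_hz * tb)
        for k, (mu, amp, sd) in enumerate(ECG_TEMPLATE):
            a = amp * qrs_scale if k in (1, 2, 3) else amp
            ecg[lo:hi] += a * np.exp(-0.5 * ((tt - mu) / sd) ** 2)
    sd = cfg.noise_sd.get("ecg", 0.0)
    if sd > 0:
        ecg = ecg + rng.normal(0.0, sd, size=n)
    r_idx = np.round(beats * cfg.ecg_fs).astype(int)
    r_idx = r_idx[r_idx < n]
    return ecg, r_idx


def generate_recording(cfg: SimConfig) -> Recording:
    """Generate one annotated synthetic recording.

    Within every annotated window the channel envelopes obey the event
    contracts: airflow <= ``apnea_floor`` x baseline during apnea and
    ``hypopnea_depth`` x baseline during hypopnea; ribcage/abdomen effort
    >= ``oa_effort_level`` x baseline during obstructive apnea and
    <= ``ca_effort_floor`` x baseline during central apnea. Output is
    bit-identical for a fixed seed.
    """
    cfg.validate()
    events = check_non_overlapping(cfg.event_list)
    rng = np.random.default_rng(cfg.seed)

    beats = _beat_times(cfg, rng)
    ecg, r_idx = _ecg_signal(cfg, beats, rng)

    n_resp = int(round(cfg.record_length_s * cfg.resp_fs))
    t = np.arange(n_resp) / cfg.resp_fs
    wave = _breath_phase_wave(cfg.breath_rate_hz * t, cfg.insp_frac)

    def flow_level(ev: EventSpec):
        if ev.kind in APNEA_KINDS:
            return cfg.apnea_floor
        if ev.kind == "hypopnea":
            return cfg.hypopnea_depth
        return None

    def effort_level(ev: EventSpec):
        if ev.kind == "central_apnea":
            return cfg.ca_effort_floor
        if ev.kind in ("obstructive_apnea", "apnea", "mixed"):
            return cfg.oa_effort_level
        if ev.kind == "hypopnea":
            return cfg.hypopnea_effort_level
        return None

    airflow = wave * _envelope(t, events, flow_level)

    # Paradoxical rib/abdomen opposition during obstructive events: the
    # ribcage wave flips sign inside OA windows (ramped outside the window).
    oa_events = [e for e in events if e.kind in ("obstructive_apnea", "apnea", "mixed")]
    sign = _envelope(t, oa_events, lambda e: -1.0)
    effort_env = _envelope(t, events, effort_level)
    ribcage = 0.9 * _breath_phase_wave(cfg.breath_rate_hz * t, cfg.insp_frac) * effort_env * sign
    abdomen = 1.0 * _breath_phase_wave(cfg.breath_rate_hz * t - 0.04, cfg.insp_frac) * effort_env

    channels = {"ecg": ecg, "airflow": airflow, "ribcage": ribcage, "abdomen": abdomen}
    for name in ("airflow", "ribcage", "abdomen"):
        sd = cfg.noise_sd.get(name, 0.0)
        if sd > 0:
            channels[name] = channels[name] + rng.normal(0.0, sd, size=n_resp)

    fs = {"ecg": cfg.ecg_fs, "airflow": cfg.resp_fs, "ribcage": cfg.resp_fs, "abdomen": cfg.resp_fs}
    annotated = [e for e in events if e.kind != "normal"]
    return Recording(channels=channels, fs=fs, annotations=annotated, true_r_peaks=r_idx)


def make_event_list(
    n_events: int,
    record_length_s: float,
    rng: np.random.Generator,
    kind_weights: dict[str, float] | None = None,
    duration_range_s: tuple[float, float] = (12.0, 30.0),
    guard_s: float = 20.0,
) -> list[EventSpec]:
    """Place ``n_events`` non-overlapping events with >= ``guard_s`` of
    quiet breathing between them, kinds drawn from ``kind_weights``."""
    if n_events == 0:
        return []
    if kind_weights is None:
        kind_weights = {"hypopnea": 0.5, "obstructive_apnea": 0.25, "central_apnea": 0.25}
    kinds = list(kind_weights)
    probs = np.array([kind_weights[k] for k in kinds], dtype=float)
    probs /= probs.sum()

    slot = record_length_s / n_events
    max_dur = duration_range_s[1]
    if slot < max_dur + guard_s:
        raise ValueError(
            f"cannot place {n_events} events of up to {max_dur:g} s with "
            f"{guard_s:g} s guards in {record_length_s:g} s"
        )
    events = []
    for i in range(n_events):
        dur = rng.uniform(*duration_range_s)
        lo = i * slot + guard_s / 2
        hi = (i + 1) * slot - dur - guard_s / 2
        onset = rng.uniform(lo, hi)
        kind = kinds[rng.choice(len(kinds), p=probs)]
        events.append(EventSpec(kind=kind, onset_s=onset, duration_s=dur))
    return events


def generate_cohort(
    n_subjects: int,
    ahi_targets: list[float],
    seed: int,
    record_length_s: float = 3600.0,
    base_config: SimConfig | None = None,
    kind_weights: dict[str, float] | None = None,
) -> list[Recording]:
    """Generate a cohort with per-subject annotated event rates.

    Each subject's (apnea + hypopnea) count is ``round(target * hours)``,
    so the realised rate is within +-0.5 events/h of the target. Subject
    seeds derive deterministically from ``seed``.
    """
    if len(ahi_targets) != n_subjects:
        raise ValueError("ahi_targets must have one entry per subject")
    if any(a < 0 for a in ahi_targets):
        raise ValueError("ahi_targets must be >= 0")
    base = base_config or SimConfig()
    hours = record_length_s / 3600.0
    recordings = []
    for i, target in enumerate(ahi_targets):
        sub_seed = (seed * 100003 + i) % (2**31 - 1)
        rng = np.random.default_rng(sub_seed)
        n_events = int(round(target * hours))
        try:
            events = make_event_list(n_events, record_length_s, rng, kind_weights)
        except ValueError as exc:
            raise ValueError(f"subject {i}: {exc}") from exc
        cfg = dataclasses.replace(
            base,
            record_length_s=record_length_s,
            event_list=events,
            seed=sub_seed,
            noise_sd=dict(base.noise_sd),
        )
        rec = generate_recording(cfg)
        rec.subject_id = f"S{i}"
        recordings.append(rec)
    return recordings
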