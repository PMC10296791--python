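"""Recording and annotation I/O: EDF, WFDB and CSV.

EDF support is a compact 16-bit codec (one data record per second, one
signal per channel at its true sampling rate). WFDB support covers
format-16 single-.dat records with per-signal samples-per-frame, which is
how mixed-rate channels (128 Hz ECG next to 8 Hz belts) are stored in one
file. Annotations travel as a CSV dialect: ``onset_s,duration_s,label``.

Channel names are mapped onto the canonical vocabulary {ecg, airflow,
ribcage, abdomen} through an editable alias table, since real PSG montages
name channels inconsistently.
"""

from __future__ import annotations

import datetime
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .types import EventSpec, Recording

__all__ = [
    "AnnotationRecord",
    "DEFAULT_ALIASES",
    "read_edf",
    "write_edf",
    "read_wfdb",
    "write_wfdb",
    "read_annotations",
    "write_annotations",
    "read_csv_dir",
    "write_csv_dir",
]

LABEL_TO_KIND = {
    "hypopnea": "hypopnea",
    "obstructive": "obstructive_apnea",
    "central": "central_apnea",
    "mixed": "mixed",
    "apnea": "apnea",
    "normal": "normal",
    "obstructive_apnea": "obstructive_apnea",
    "central_apnea": "central_apnea",
}

DEFAULT_ALIASES: dict[str, str] = {
    "ecg": "ecg", "ekg": "ecg", "ecg1": "ecg", "ecg i": "ecg",
    "airflow": "airflow", "flow": "airflow", "oronasal": "airflow",
    "nasal flow": "airflow", "oronasal airflow": "airflow",
    "ribcage": "ribcage", "rib cage": "ribcage", "thor": "ribcage",
    "thorax": "ribcage", "chest": "ribcage", "thor res": "ribcage",
    "abdomen": "abdomen", "abdo": "abdomen", "abd": "abdomen", "abdo res": "abdomen",
}


@dataclass(frozen=True)
class AnnotationRecord:
    """One labelled event interval as found in an annotation file."""

    onset_s: float
    duration_s: float
    label: str

    def __post_init__(self) -> None:
        if self.onset_s < 0:
            raise ValueError("onset_s must be >= 0")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be > 0")

    def to_event(self) -> EventSpec:
        kind = LABEL_TO_KIND.get(self.label.strip().lower())
        if kind is None:
            raise ValueError(f"unknown annotation label: {self.label!r}")
        return EventSpec(kind=kind, onset_s=self.onset_s, duration_s=self.duration_s)


def _canonical(name: str, aliases: dict[str, str] | None) -> str:
    table = DEFAULT_ALIASES if aliases is None else aliases
    return table.get(name.strip().lower(), name.strip().lower())


# ---------------------------------------------------------------------------
# annotations (CSV)
# ---------------------------------------------------------------------------

def write_annotations(annotations: list, path) -> None:
    """Write events/annotation records as CSV (onset_s,duration_s,label)."""
    rows = []
    for a in annotations:
        label = a.label if isinstance(a, AnnotationRecord) else a.kind
        rows.append({"onset_s": a.onset_s, "duration_s": a.duration_s, "label": label})
    pd.DataFrame(rows, columns=["onset_s", "duration_s", "label"]).to_csv(path, index=False)


def read_annotations(path) -> list[AnnotationRecord]:
    """Read an annotation CSV; returns records sorted by onset."""
    df = pd.read_csv(path)
    if df.empty:
        return []
    recs = [
        AnnotationRecord(float(r.onset_s), float(r.duration_s), str(r.label))
        for r in df.itertuples()
    ]
    return sorted(recs, key=lambda r: r.onset_s)


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def _edf_ascii(value, width: int) -> bytes:
    s = f"{value}"
    if len(s) > width:
        s = s[:width]
    return s.ljust(width).encode("ascii")


def _edf_float(value: float, width: int = 8) -> bytes:
    for fmt in (f"{value:.10g}", f"{value:.6g}", f"{value:.4g}", f"{value:.2g}"):
        if len(fmt) <= width:
            return fmt.ljust(width).encode("ascii")
    return fmt[:width].encode("ascii")


def write_edf(rec: Recording, path) -> None:
    """Write a recording as EDF (16-bit), one signal per channel.

    Each data record spans 1 s, so every channel's sampling rate must be a
    positive integer. The record is zero-padded to a whole second.
    """
    path = Path(path)
    names = list(rec.channels)
    for c in names:
        if abs(rec.fs[c] - round(rec.fs[c])) > 1e-9 or rec.fs[c] <= 0:
            raise ValueError(f"EDF writer requires integer fs; channel {c!r} has {rec.fs[c]}")
    n_rec = int(np.ceil(max(len(rec.channels[c]) / rec.fs[c] for c in names)))

    phys_min, phys_max, digitized = {}, {}, {}
    for c in names:
        x = np.asarray(rec.channels[c], dtype=float)
        spr = int(round(rec.fs[c]))
        target = n_rec * spr
        if len(x) < target:
            x = np.pad(x, (0, target - len(x)))
        amp = max(np.max(np.abs(x)), 1e-12)
        # digitize against the value the 8-char header field can actually
        # carry, so the round trip is exact to one quantization step
        amp = float(_edf_float(amp).decode().strip())
        phys_min[c], phys_max[c] = -amp, amp
        digitized[c] = np.clip(np.round(x / amp * 32767), -32767, 32767).astype("<i2")

    ns = len(names)
    now = datetime.datetime(2000, 1, 1)
    header = b"".join([
        _edf_ascii("0", 8),
        _edf_ascii("X X X X", 80),
        _edf_ascii("Startdate X X X X", 80),
        _edf_ascii(now.strftime("%d.%m.%y"), 8),
        _edf_ascii(now.strftime("%H.%M.%S"), 8),
        _edf_ascii(256 * (1 + ns), 8),
        _edf_ascii("", 44),
        _edf_ascii(n_rec, 8),
        _edf_ascii(1, 8),
        _edf_ascii(ns, 4),
    ])
    header += b"".join(_edf_ascii(c, 16) for c in names)
    header += b"".join(_edf_ascii("", 80) for _ in names)
    header += b"".join(_edf_ascii("au", 8) for _ in names)
    header += b"".join(_edf_float(phys_min[c]) for c in names)
    header += b"".join(_edf_float(phys_max[c]) for c in names)
    header += b"".join(_edf_ascii(-32767, 8) for _ in names)
    header += b"".join(_edf_ascii(32767, 8) for _ in names)
    header += b"".join(_edf_ascii("", 80) for _ in names)
    header += b"".join(_edf_ascii(int(round(rec.fs[c])), 8) for c in names)
    header += b"".join(_edf_ascii("", 32) for _ in names)

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_rec):
            for c in names:
                spr = int(round(rec.fs[c]))
                fh.write(digitized[c][r * spr:(r + 1) * spr].tobytes())


def read_edf(
    path,
    aliases: dict[str, str] | None = None,
    required: tuple[str, ...] = (),
    stage: str = "pipeline",
) -> Recording:
    """Read an EDF/EDF+ file into a :class:`Recording`.

    ``required`` lists canonical channels the caller's pipeline stage needs;
    a missing one raises an error naming both the stage and the channel.
    Unmapped channels are retained under their own (lowercased) names.
    """
    path = Path(path)
    with open(path, "rb") as fh:
        head = fh.read(256)
        if len(head) < 256:
            raise ValueError(f"{path} is not a valid EDF file (truncated header)")
        n_rec = int(head[236:244].decode("ascii").strip())
        rec_dur = float(head[244:252].decode("ascii").strip())
        ns = int(head[252:256].decode("ascii").strip())
        sig = fh.read(256 * ns)
        labels = [sig[16 * i:16 * (i + 1)].decode("ascii").strip() for i in range(ns)]
        off = 16 * ns + 80 * ns + 8 * ns
        pmin = [float(sig[off + 8 * i: off + 8 * (i + 1)].decode().strip()) for i in range(ns)]
        off += 8 * ns
        pmax = [float(sig[off + 8 * i: off + 8 * (i + 1)].decode().strip()) for i in range(ns)]
        off += 8 * ns
        dmin = [int(sig[off + 8 * i: off + 8 * (i + 1)].decode().strip()) for i in range(ns)]
        off += 8 * ns
        dmax = [int(sig[off + 8 * i: off + 8 * (i + 1)].decode().strip()) for i in range(ns)]
        off += 8 * ns + 80 * ns
        spr = [int(sig[off + 8 * i: off + 8 * (i + 1)].decode().strip()) for i in range(ns)]
        data = np.frombuffer(fh.read(), dtype="<i2")

    rec_len = sum(spr)
    if len(data) < n_rec * rec_len:
        n_rec = len(data) // rec_len
    data = data[: n_rec * rec_len].reshape(n_rec, rec_len)

    channels, fs = {}, {}
    col = 0
    for i, label in enumerate(labels):
        raw = data[:, col: col + spr[i]].reshape(-1).astype(float)
        col += spr[i]
        scale = (pmax[i] - pmin[i]) / (dmax[i] - dmin[i])
        phys = (raw - dmin[i]) * scale + pmin[i]
        name = _canonical(label, aliases)
        channels[name] = phys
        fs[name] = spr[i] / rec_dur

    rec = Recording(channels=channels, fs=fs)
    rec.require(required, stage)
    return rec


# ---------------------------------------------------------------------------
# WFDB (header + format-16 signal file)
# ---------------------------------------------------------------------------

def write_wfdb(rec: Recording, record_path) -> None:
    """Write a recording as a WFDB record (format 16, one .dat).

    Channels are interleaved frame by frame at the lowest sampling rate;
    faster channels store ``fs / frame_fs`` samples per frame. Annotations,
    if any, are written next to the record as ``<name>.anno.csv``.
    """
    record_path = Path(record_path)
    names = list(rec.channels)
    frame_fs = min(rec.fs[c] for c in names)
    spf = {}
    for c in names:
        ratio = rec.fs[c] / frame_fs
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError(f"fs of {c!r} is not an integer multiple of the frame rate")
        spf[c] = int(round(ratio))
    n_frames = min(len(rec.channels[c]) // spf[c] for c in names)

    gains, digitized = {}, {}
    for c in names:
        x = np.asarray(rec.channels[c][: n_frames * spf[c]], dtype=float)
        amp = max(np.max(np.abs(x)), 1e-12)
        gains[c] = 32000.0 / amp
        digitized[c] = np.clip(np.round(x * gains[c]), -32768, 32767).astype("<i2")

    dat_name = record_path.name + ".dat"
    lines = [f"{record_path.name} {len(names)} {frame_fs:g} {n_frames}"]
    for c in names:
        fmt = f"16x{spf[c]}" if spf[c] > 1 else "16"
        first = int(digitized[c][0]) if len(digitized[c]) else 0
        lines.append(f"{dat_name} {fmt} {gains[c]:.6f}(0)/au 16 0 {first} 0 0 {c}")
    record_path.with_suffix(".hea").write_text("\n".join(lines) + "\n")

    frame = np.empty((n_frames, sum(spf[c] for c in names)), dtype="<i2")
    col = 0
    for c in names:
        frame[:, col: col + spf[c]] = digitized[c].reshape(n_frames, spf[c])
        col += spf[c]
    (record_path.parent / dat_name).write_bytes(frame.tobytes())

    if rec.annotations:
        write_annotations(rec.annotations, record_path.with_suffix(".anno.csv"))


def read_wfdb(
    record_path,
    aliases: dict[str, str] | None = None,
    required: tuple[str, ...] = (),
    stage: str = "pipeline",
) -> Recording:
    """Read a WFDB record (format 16 / 16xN) written by :func:`write_wfdb`
    or any compatible single-.dat record."""
    record_path = Path(record_path)
    hea = record_path.with_suffix(".hea")
    if not hea.exists():
        raise FileNotFoundError(f"no WFDB header: {hea}")
    lines = [ln for ln in hea.read_text().splitlines() if ln.strip() and not ln.startswith("#")]
    head = lines[0].split()
    n_sig, frame_fs, n_frames = int(head[1]), float(head[2]), int(head[3])

    sig_lines = lines[1: 1 + n_sig]
    dat_files, spfs, gains, names = [], [], [], []
    for i, ln in enumerate(sig_lines):
        parts = ln.split()
        dat_files.append(parts[0])
        fmt = parts[1]
        spf = int(fmt.split("x")[1]) if "x" in fmt else 1
        spfs.append(spf)
        gain_field = parts[2].split("(")[0].split("/")[0]
        gains.append(float(gain_field))
        names.append(" ".join(parts[8:]) if len(parts) > 8 else f"sig{i}")
    if len(set(dat_files)) != 1:
        raise ValueError("only single-.dat WFDB records are supported")

    data = np.frombuffer((record_path.parent / dat_files[0]).read_bytes(), dtype="<i2")
    frame_len = sum(spfs)
    n_frames = min(n_frames, len(data) // frame_len)
    data = data[: n_frames * frame_len].reshape(n_frames, frame_len)

    channels, fs = {}, {}
    col = 0
    for i, raw_name in enumerate(names):
        name = _canonical(raw_name, aliases)
        channels[name] = data[:, col: col + spfs[i]].reshape(-1).astype(float) / gains[i]
        fs[name] = frame_fs * spfs[i]
        col += spfs[i]

    anno_path = record_path.with_suffix(".anno.csv")
    annotations = []
    if anno_path.exists():
        annotations = [a.to_event() for a in read_annotations(anno_path)]

    rec = Recording(channels=channels, fs=fs, annotations=annotations)
    rec.require(required, stage)
    return rec


# ---------------------------------------------------------------------------
# CSV directory dialect
# ---------------------------------------------------------------------------

def write_csv_dir(rec: Recording, directory) -> None:
    """One ``<channel>.csv`` (time_s,value) per channel plus annotations.csv."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for c, x in rec.channels.items():
        t = np.arange(len(x)) / rec.fs[c]
        pd.DataFrame({"time_s": t, "value": x}).to_csv(directory / f"{c}.csv", index=False)
    write_annotations(rec.annotations, directory / "annotations.csv")


def read_csv_dir(directory, aliases: dict[str, str] | None = None) -> Recording:
    directory = Path(directory)
    channels, fs = {}, {}
    for f in sorted(directory.glob("*.csv")):
        if f.name == "annotations.csv":
            continue
        df = pd.read_csv(f)
        name = _canonical(f.stem, aliases)
        channels[name] = df["value"].to_numpy(dtype=float)
        dt = np.diff(df["time_s"].to_numpy())
        if len(dt) == 0 or np.any(dt <= 0):
            warnings.warn(f"cannot infer fs for {f.name}; assuming 1 Hz")
            fs[name] = 1.0
        else:
            fs[name] = 1.0 / float(np.median(dt))
    annotations = []
    anno = directory / "annotations.csv"
    if anno.exists():
        annotations = [a.to_event() for a in read_annotations(anno)]
    return Recording(channels=channels, fs=fs, annotations=annotations)
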