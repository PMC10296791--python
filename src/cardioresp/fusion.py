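"""Two-lead state-trajectory fusion.

The simultaneously sampled ribcage and abdomen effort leads form a planar
state trajectory p_i = (x_i, y_i). For each state point the Euclidean
distance to its closest other state point becomes sample i of a new 1-D
"fusion" series. During obstructive apnea the belts keep moving and the
trajectory stays spread out (large nearest-neighbour distances); during
central apnea both leads collapse to sensor noise and the trajectory
shrinks to a tight cluster (small distances) — that contrast is what the
downstream sequence classifier learns.

The nearest-neighbour search is exact (brute force); an optional
Theiler-style temporal exclusion window widens the "self" exclusion.
"""

from __future__ import annotations

import warnings

import numpy as np

from .types import FusionSeries, Segment

__all__ = ["fuse", "fuse_segment"]


def fuse(x: np.ndarray, y: np.ndarray, exclusion_w: int = 0) -> FusionSeries:
    """Nearest-state-point distance series of the (x, y) trajectory.

    d_i = min over j with |j - i| > exclusion_w of ||p_i - p_j||. Ties go
    to the smallest j (irrelevant to the distance value itself).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("leads must have equal length")
    n = len(x)
    if exclusion_w < 0:
        raise ValueError("exclusion_w must be >= 0")
    if n <= exclusion_w + 1:
        raise ValueError(
            f"series of length {n} has no admissible neighbour with "
            f"exclusion window {exclusion_w}"
        )
    pts = np.column_stack([x, y])
    diff = pts[:, None, :] - pts[None, :, :]
    dist2 = np.einsum("ijk,ijk->ij", diff, diff)
    idx = np.arange(n)
    excluded = np.abs(idx[:, None] - idx[None, :]) <= exclusion_w
    dist2[excluded] = np.inf
    d = np.sqrt(np.min(dist2, axis=1))
    return FusionSeries(d=d)


def fuse_segment(
    seg: Segment,
    normalization: str = "zscore",
    exclusion_w: int = 0,
    leads: tuple[str, str] = ("ribcage", "abdomen"),
) -> FusionSeries:
    """Fuse a segment's effort leads into one distance series.

    With ``normalization="zscore"`` each lead is standardized within the
    segment first (effort-belt gains are arbitrary); a zero-variance lead
    triggers a fallback to no normalization, with a warning.
    """
    a, b = leads
    if a not in seg.channels or b not in seg.channels:
        raise KeyError(f"segment lacks lead {a!r} or {b!r}")
    if seg.fs[a] != seg.fs[b]:
        raise ValueError("leads must share a sampling rate")
    x = np.asarray(seg.channels[a], dtype=float)
    y = np.asarray(seg.channels[b], dtype=float)
    if normalization not in ("none", "zscore"):
        raise ValueError(f"unknown normalization: {normalization!r}")
    applied = normalization
    if normalization == "zscore":
        sx, sy = np.std(x), np.std(y)
        if sx == 0 or sy == 0:
            warnings.warn("zero-variance lead; falling back to normalization 'none'")
            applied = "none"
        else:
            x = (x - np.mean(x)) / sx
            y = (y - np.mean(y)) / sy
    out = fuse(x, y, exclusion_w=exclusion_w)
    out.source = f"{a}+{b}"
    out.normalization = applied
    return out


def harvest_subtype_sequences(
    recordings,
    window_s: float = 10.0,
    overlap_frac: float = 0.9,
    normalization: str = "zscore",
    exclusion_w: int = 0,
):
    """Fused sequences for every obstructive/central-labelled window.

    Annotated recordings are sliced with the dense (90 %-overlap) window
    schedule used for subtype training, and each window whose majority
    label is obstructive or central apnea is fused. Returns
    ``(sequences, labels)`` with label 1 = obstructive.
    """
    from .preprocess import segmentize  # local import avoids a cycle at module load

    seqs: list[np.ndarray] = []
    labels: list[int] = []
    for rec in recordings:
        segments = segmentize(
            rec, window_s=window_s, overlap_frac=overlap_frac,
            channels=["ribcage", "abdomen"],
        )
        for seg in segments:
            if seg.label not in ("obstructive_apnea", "central_apnea"):
                continue
            fs = fuse_segment(seg, normalization=normalization, exclusion_w=exclusion_w)
            seqs.append(fs.d)
            labels.append(1 if seg.label == "obstructive_apnea" else 0)
    if not seqs:
        return np.empty((0, 0)), np.empty(0, dtype=int)
    return np.vstack(seqs), np.asarray(labels)
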