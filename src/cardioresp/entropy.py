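"""Entropy features for RR-interval (and related) series.

Six estimators: Shannon, Renyi and Tsallis entropies on an equal-width
histogram; transfer entropy on symbolized series; Shannon entropy of the
horizontal-visibility-graph (HVG) degree distribution; and an "alphabet"
entropy over words of sign-of-difference symbols. Natural logarithms
throughout, so every value is in nats.

Defaults (bin counts, alpha, q, lags, word length) are package choices
exposed in :class:`EntropyConfig`; none is a claim about an external
reference definition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "EntropyConfig",
    "shannon_entropy",
    "renyi_entropy",
    "tsallis_entropy",
    "transfer_entropy",
    "degree_distribution_entropy",
    "alphabet_entropy",
    "hvg_degrees",
    "entropy_features",
]


@dataclass
class EntropyConfig:
    n_bins: int = 10        # histogram estimators
    renyi_alpha: float = 2.0
    tsallis_q: float = 2.0
    te_lag: int = 1
    te_bins: int = 3
    word_length: int = 3    # alphabet entropy
    hvg_max_nodes: int = 4096

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if self.word_length < 1:
            raise ValueError("word_length must be >= 1")
        if self.renyi_alpha == 1 or self.tsallis_q == 1:
            raise ValueError("alpha and q must differ from 1")


def _hist_probs(x: np.ndarray, n_bins: int) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 samples")
    if np.ptp(x) == 0:
        return np.array([1.0])  # single occupied bin
    counts, _ = np.histogram(x, bins=n_bins, range=(np.min(x), np.max(x)))
    p = counts / counts.sum()
    return p[p > 0]


def _shannon_of(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-np.sum(p * np.log(p)))


def shannon_entropy(x, cfg: EntropyConfig | None = None) -> float:
    """Shannon entropy of the equal-width histogram of ``x`` (nats)."""
    cfg = cfg or EntropyConfig()
    return _shannon_of(_hist_probs(x, cfg.n_bins))


def renyi_entropy(x, alpha: float | None = None, cfg: EntropyConfig | None = None) -> float:
    """Renyi entropy: log(sum p^alpha) / (1 - alpha)."""
    cfg = cfg or EntropyConfig()
    a = cfg.renyi_alpha if alpha is None else alpha
    if a == 1:
        raise ValueError("alpha must differ from 1")
    p = _hist_probs(x, cfg.n_bins)
    return float(np.log(np.sum(p ** a)) / (1.0 - a))


def tsallis_entropy(x, q: float | None = None, cfg: EntropyConfig | None = None) -> float:
    """Tsallis entropy: (1 - sum p^q) / (q - 1)."""
    cfg = cfg or EntropyConfig()
    qq = cfg.tsallis_q if q is None else q
    if qq == 1:
        raise ValueError("q must differ from 1")
    p = _hist_probs(x, cfg.n_bins)
    return float((1.0 - np.sum(p ** qq)) / (qq - 1.0))


# ---------------------------------------------------------------------------
# transfer entropy
# ---------------------------------------------------------------------------

def _symbolize(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Quantile-bin a series into integer symbols 0..n_bins-1.

    Series that already take few discrete values (<= n_bins uniques) keep
    their own alphabet, which makes the estimator exact on symbolic inputs.
    """
    x = np.asarray(x, dtype=float)
    uniq = np.unique(x)
    if len(uniq) <= n_bins:
        return np.searchsorted(uniq, x)
    edges = np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1])
    return np.searchsorted(edges, x, side="right")


def transfer_entropy(src, dst, cfg: EntropyConfig | None = None) -> float:
    """Plug-in transfer entropy TE(src -> dst) in nats.

    TE = sum p(d', d, s) log[ p(d'|d, s) / p(d'|d) ] with d' = dst one lag
    ahead. Quantifies how much the source's present reduces uncertainty
    about the destination's next value beyond the destination's own past.
    """
    cfg = cfg or EntropyConfig()
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    if len(src) != len(dst):
        raise ValueError("src and dst must have equal length")
    if len(src) < 50:
        raise ValueError("transfer entropy requires length >= 50")
    if np.ptp(src) == 0 or np.ptp(dst) == 0:
        warnings.warn("degenerate (constant) series; transfer entropy = 0")
        return 0.0
    s = _symbolize(src, cfg.te_bins)
    d = _symbolize(dst, cfg.te_bins)
    lag = cfg.te_lag
    d_next, d_now, s_now = d[lag:], d[:-lag], s[:-lag]

    n = len(d_next)
    base = cfg.te_bins if cfg.te_bins > max(d.max(), s.max()) else max(d.max(), s.max()) + 1
    joint3 = np.zeros((base, base, base))
    np.add.at(joint3, (d_next, d_now, s_now), 1.0)
    joint3 /= n
    p_ds = joint3.sum(axis=0)        # p(d, s)
    p_nd = joint3.sum(axis=2)        # p(d', d)
    p_d = joint3.sum(axis=(0, 2))    # p(d)

    te = 0.0
    nz = np.argwhere(joint3 > 0)
    for dn, dd, ss in nz:
        p3 = joint3[dn, dd, ss]
        te += p3 * np.log(p3 * p_d[dd] / (p_ds[dd, ss] * p_nd[dn, dd]))
    return float(max(te, 0.0))


# ---------------------------------------------------------------------------
# horizontal visibility graph
# ---------------------------------------------------------------------------

def hvg_degrees(x) -> np.ndarray:
    """Node degrees of the horizontal visibility graph of ``x``.

    Nodes i < j are linked iff every intermediate sample lies strictly
    below both endpoints (ties block visibility). Adjacent samples are
    always linked.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("HVG needs at least 3 samples")
    deg = np.zeros(n, dtype=int)
    for i in range(n - 1):
        deg[i] += 1
        deg[i + 1] += 1  # adjacent edge
        max_mid = x[i + 1]
        for j in range(i + 2, n):
            if max_mid < x[i] and max_mid < x[j]:
                deg[i] += 1
                deg[j] += 1
            max_mid = max(max_mid, x[j])
            if max_mid >= x[i]:
                break
    return deg


def degree_distribution_entropy(x) -> float:
    """Shannon entropy of the HVG empirical degree distribution (nats)."""
    deg = hvg_degrees(x)
    _, counts = np.unique(deg, return_counts=True)
    return _shannon_of(counts / counts.sum())


# ---------------------------------------------------------------------------
# alphabet entropy
# ---------------------------------------------------------------------------

def alphabet_entropy(x, cfg: EntropyConfig | None = None) -> float:
    """Shannon entropy of sign-of-difference words (nats).

    Successive differences are symbolized into {-, 0, +} with a dead band
    of 0.1 x SD(diffs); words of ``word_length`` consecutive symbols are
    counted and their distribution's entropy returned.
    """
    cfg = cfg or EntropyConfig()
    x = np.asarray(x, dtype=float)
    L = cfg.word_length
    if len(x) < L + 1:
        raise ValueError(f"need at least word_length + 1 = {L + 1} samples")
    d = np.diff(x)
    tol = 0.1 * np.std(d)
    sym = np.where(d > tol, 2, np.where(d < -tol, 0, 1))
    if len(sym) < L:
        raise ValueError("series too short for the requested word length")
    words = np.lib.stride_tricks.sliding_window_view(sym, L)
    codes = words @ (3 ** np.arange(L))
    _, counts = np.unique(codes, return_counts=True)
    return _shannon_of(counts / counts.sum())


def entropy_features(
    rr_ms: np.ndarray,
    edr: np.ndarray | None = None,
    cfg: EntropyConfig | None = None,
) -> dict[str, float]:
    """The six entropy features of an RR series as a flat mapping.

    Transfer entropy is computed respiration-to-heart, TE(EDR -> RR), on
    the per-beat aligned pair; NaN when either side is missing or short.
    """
    cfg = cfg or EntropyConfig()
    rr_ms = np.asarray(rr_ms, dtype=float)
    out = {
        "shannon_en": np.nan, "renyi_en": np.nan, "tsallis_en": np.nan,
        "transfer_en": np.nan, "hvg_degree_en": np.nan, "alphabet_en": np.nan,
    }
    if len(rr_ms) >= 2:
        out["shannon_en"] = shannon_entropy(rr_ms, cfg)
        out["renyi_en"] = renyi_entropy(rr_ms, cfg=cfg)
        out["tsallis_en"] = tsallis_entropy(rr_ms, cfg=cfg)
    if len(rr_ms) >= 3:
        out["hvg_degree_en"] = degree_distribution_entropy(rr_ms)
    if len(rr_ms) >= cfg.word_length + 1:
        out["alphabet_en"] = alphabet_entropy(rr_ms, cfg)
    if edr is not None and len(edr) == len(rr_ms) and len(rr_ms) >= 50:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out["transfer_en"] = transfer_entropy(edr, rr_ms, cfg)
    return out
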