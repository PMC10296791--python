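"""Entropy estimators: closed forms, limits, oracles and invariances."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cardioresp.entropy import (
    EntropyConfig,
    alphabet_entropy,
    degree_distribution_entropy,
    hvg_degrees,
    renyi_entropy,
    shannon_entropy,
    transfer_entropy,
    tsallis_entropy,
)


def uniform_over_bins(k, reps=5):
    """A series filling k equal-width bins uniformly."""
    return np.tile(np.arange(k, dtype=float), reps)


def test_shannon_uniform_is_log_k():
    for k in (2, 5, 10):
        x = uniform_over_bins(k)
        assert shannon_entropy(x, EntropyConfig(n_bins=k)) == pytest.approx(np.log(k))


def test_shannon_constant_is_zero():
    assert shannon_entropy(np.full(50, 3.3)) == 0.0


def test_renyi_uniform_alpha_independent():
    x = uniform_over_bins(8)
    cfg = EntropyConfig(n_bins=8)
    for alpha in (0.5, 2.0, 5.0):
        assert renyi_entropy(x, alpha, cfg) == pytest.approx(np.log(8))


def test_renyi_tsallis_limits_converge_to_shannon(rng):
    x = rng.standard_normal(500)
    h = shannon_entropy(x)
    assert abs(renyi_entropy(x, 1.001) - h) < 0.01
    assert abs(tsallis_entropy(x, 1.001) - h) < 0.01


def test_transfer_entropy_copy_channel_is_log3(rng):
    """dst_{t+1} = src_t with a 3-symbol uniform source carries log 3 nats."""
    n = 6000
    src = rng.integers(0, 3, size=n).astype(float)
    dst = np.roll(src, 1)
    te = transfer_entropy(src, dst, EntropyConfig(te_bins=3, te_lag=1))
    assert te == pytest.approx(np.log(3), rel=0.05)


def test_transfer_entropy_fully_self_predicted_dst_is_zero(rng):
    """When dst_{t+1} is a function of dst_t alone, conditioning on the
    source adds nothing."""
    n = 2000
    dst = np.tile([0.0, 1.0], n // 2)
    src = rng.standard_normal(n)
    te = transfer_entropy(src, dst, EntropyConfig(te_bins=2))
    assert te == pytest.approx(0.0, abs=1e-9)


def test_transfer_entropy_constant_series_warns_zero(rng):
    with pytest.warns(UserWarning):
        te = transfer_entropy(np.ones(100), rng.standard_normal(100))
    assert te == 0.0


def test_transfer_entropy_matches_brute_force_counts(rng):
    """Plug-in estimate equals a dictionary-of-triplets oracle."""
    n = 400
    src = rng.integers(0, 3, size=n).astype(float)
    dst = rng.integers(0, 3, size=n).astype(float)
    te = transfer_entropy(src, dst, EntropyConfig(te_bins=3, te_lag=1))

    from collections import Counter
    s, d = src.astype(int), dst.astype(int)
    c3 = Counter(zip(d[1:], d[:-1], s[:-1]))
    c_ds = Counter(zip(d[:-1], s[:-1]))
    c_nd = Counter(zip(d[1:], d[:-1]))
    c_d = Counter(d[:-1])
    m = n - 1
    expected = 0.0
    for (dn, dd, ss), cnt in c3.items():
        expected += (cnt / m) * np.log((cnt / m) * (c_d[dd] / m)
                                       / ((c_ds[dd, ss] / m) * (c_nd[dn, dd] / m)))
    assert te == pytest.approx(max(expected, 0.0), abs=1e-12)


def _hvg_brute_force_degrees(x):
    """O(n^3) literal edge test: i~j iff all between are strictly below both."""
    n = len(x)
    deg = np.zeros(n, dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            if all(x[k] < min(x[i], x[j]) for k in range(i + 1, j)):
                deg[i] += 1
                deg[j] += 1
    return deg


def test_hvg_monotone_series_is_path_graph():
    for n in (5, 8, 12):
        x = np.arange(n, dtype=float)
        h = degree_distribution_entropy(x)
        p1, p2 = 2 / n, (n - 2) / n
        assert h == pytest.approx(-(p1 * np.log(p1) + p2 * np.log(p2)))


def test_hvg_constant_series_is_path_graph():
    x = np.zeros(10)
    np.testing.assert_array_equal(hvg_degrees(x), [1] + [2] * 8 + [1])


def test_hvg_matches_brute_force_small_series(rng):
    for _ in range(200):
        n = int(rng.integers(3, 13))
        x = rng.standard_normal(n)
        np.testing.assert_array_equal(hvg_degrees(x), _hvg_brute_force_degrees(x))


def test_alphabet_entropy_monotone_series_zero():
    assert alphabet_entropy(np.arange(50, dtype=float)) == 0.0


def test_alphabet_entropy_alternating_log2():
    x = np.array([0.0, 1.0] * 30)
    h = alphabet_entropy(x, EntropyConfig(word_length=2))
    assert h == pytest.approx(np.log(2))


def test_alphabet_entropy_iid_noise_word1(rng):
    """On i.i.d. noise the single-symbol entropy matches the closed form
    for the +/0/- partition with the 0.1-SD dead band."""
    from scipy.stats import norm

    x = rng.standard_normal(5000)
    h = alphabet_entropy(x, EntropyConfig(word_length=1))
    p0 = norm.cdf(0.1) - norm.cdf(-0.1)   # dead band is 0.1 x SD(diffs)
    pm = (1 - p0) / 2
    expected = -(p0 * np.log(p0) + 2 * pm * np.log(pm))
    assert h == pytest.approx(expected, rel=0.03)


@settings(derandomize=True, max_examples=40, deadline=None)
@given(st.lists(st.floats(-100, 100), min_size=10, max_size=80), st.integers(0, 2**31 - 1))
def test_histogram_entropies_properties(values, seed):
    """Non-negativity, the log(n_bins) bound and permutation invariance."""
    x = np.asarray(values)
    cfg = EntropyConfig(n_bins=8)
    h = shannon_entropy(x, cfg)
    assert 0.0 <= h <= np.log(8) + 1e-12
    for alpha in (0.5, 2.0, 4.0):
        assert renyi_entropy(x, alpha, cfg) >= -1e-12
    # Renyi is non-increasing in alpha
    r = [renyi_entropy(x, a, cfg) for a in (0.5, 1.5, 3.0, 6.0)]
    assert all(a >= b - 1e-9 for a, b in zip(r, r[1:]))
    perm = np.random.default_rng(seed).permutation(x)
    assert shannon_entropy(perm, cfg) == pytest.approx(h, abs=1e-12)
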