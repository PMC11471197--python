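"""Brute-force reference implementations used to verify the bitap matcher
and the statistics. Deliberately independent of the package internals."""

from math import comb

import numpy as np


def _to_array(s: str) -> np.ndarray:
    return np.frombuffer(s.encode(), dtype="S1")


def hamming_occurrences(pattern: str, text: str, k: int) -> list[int]:
    """End positions (exclusive) where pattern matches a length-m window of
    text with at most k mismatching positions. Any non-equal byte (including
    N) is a mismatch."""
    m, n = len(pattern), len(text)
    if n < m:
        return []
    p = _to_array(pattern)
    t = _to_array(text)
    windows = np.lib.stride_tricks.sliding_window_view(t, m)
    mism = (windows != p).sum(axis=1)
    return [int(j) + m for j in np.flatnonzero(mism <= k)]


def edit_occurrences(pattern: str, text: str, k: int) -> list[int]:
    """End positions j >= 1 where some substring of text ending at j matches
    pattern with edit distance <= k (semi-global DP, free start)."""
    m, n = len(pattern), len(text)
    p = _to_array(pattern)
    t = _to_array(text)
    j_idx = np.arange(n + 1)
    prev = np.zeros(n + 1, dtype=int)  # D[0, :] = 0
    for i in range(1, m + 1):
        cost = np.empty(n + 1, dtype=int)
        cost[0] = 0
        cost[1:] = (t != p[i - 1]).astype(int)
        tmp = np.empty(n + 1, dtype=int)
        tmp[0] = i
        tmp[1:] = np.minimum(prev[:-1] + cost[1:], prev[1:] + 1)
        # horizontal (insertion-in-text) dependency via the accumulate trick
        cur = np.minimum.accumulate(tmp - j_idx) + j_idx
        prev = cur
    return [int(j) for j in range(1, n + 1) if prev[j] <= k]


def binomial_upper_tail(obs: int, n: int, p: float) -> float:
    """P(X >= obs) for X ~ Binomial(n, p) by direct summation."""
    return sum(comb(n, i) * p**i * (1 - p) ** (n - i) for i in range(obs, n + 1))


def bh_stepup(pvalues) -> np.ndarray:
    """Textbook Benjamini-Hochberg step-up q-values."""
    p = np.asarray(pvalues, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    q_sorted = p[order] * n / np.arange(1, n + 1)
    for i in range(n - 2, -1, -1):
        q_sorted[i] = min(q_sorted[i], q_sorted[i + 1])
    q = np.empty(n)
    q[order] = np.clip(q_sorted, 0, 1)
    return q
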