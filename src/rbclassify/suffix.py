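"""Suffix-array construction by prefix doubling.

Desk-scale databases (up to a few megabases) sort comfortably with a
numpy-vectorized prefix-doubling pass, O(n log^2 n) worst case. The
sentinel appended per database sequence guarantees all suffixes are
distinct, so the loop always terminates with a full ordering.
"""

from __future__ import annotations

import numpy as np


def suffix_array(codes: np.ndarray) -> np.ndarray:
    """Suffix array (0-based start offsets in lexicographic suffix order)."""
    codes = np.asarray(codes, dtype=np.int64)
    n = codes.size
    if n == 0:
        return np.empty(0, dtype=np.int64)
    if n == 1:
        return np.zeros(1, dtype=np.int64)
    rank = codes
    k = 1
    while True:
        key_lo = np.full(n, -1, dtype=np.int64)
        key_lo[: n - k] = rank[k:]
        order = np.lexsort((key_lo, rank))
        hi = rank[order]
        lo = key_lo[order]
        changed = np.empty(n, dtype=np.int64)
        changed[0] = 0
        changed[1:] = (hi[1:] != hi[:-1]) | (lo[1:] != lo[:-1])
        new_rank_sorted = np.cumsum(changed)
        if new_rank_sorted[-1] == n - 1:
            return order.astype(np.int64)
        new_rank = np.empty(n, dtype=np.int64)
        new_rank[order] = new_rank_sorted
        rank = new_rank
        k *= 2
        if k >= n:
            # all suffixes compared to full length; ranks must be distinct
            raise ValueError("input has equal suffixes (missing sentinel?)")


def bwt_from_sa(codes: np.ndarray, sa: np.ndarray) -> np.ndarray:
    """BWT characters: the character preceding each sorted suffix."""
    codes = np.asarray(codes, dtype=np.int64)
    return codes[(sa - 1) % codes.size]


def inverse_bwt(bwt_codes: np.ndarray, first_row: int = 0) -> np.ndarray:
    """Reconstruct the text from its BWT (test oracle for small inputs)."""
    bwt_codes = np.asarray(bwt_codes, dtype=np.int64)
    n = bwt_codes.size
    counts = np.bincount(bwt_codes)
    c_arr = np.concatenate(([0], np.cumsum(counts)))
    occ = np.zeros_like(counts)
    lf = np.empty(n, dtype=np.int64)
    for i in range(n):
        c = bwt_codes[i]
        lf[i] = c_arr[c] + occ[c]
        occ[c] += 1
    out = np.empty(n, dtype=np.int64)
    p = first_row
    for i in range(n - 1, -1, -1):
        out[i] = bwt_codes[p]
        p = lf[p]
    return np.roll(out, -1)
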