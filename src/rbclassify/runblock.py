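"""Run-block compressed sequences.

A text of length ``n`` is cut into ``m = ceil(n/b)`` fixed-size blocks.
A block consisting of a single repeated character (a *run block*) is
stored as one character in the run subsequence ``T_R``; every other
block is copied verbatim into the plain subsequence ``T_P``. A bit
vector ``B_R`` over the blocks records which ones were run blocks. Both
subsequences live in balanced wavelet trees, so a rank query on the
original text decomposes into one bit-vector rank on ``B_R`` plus at
most two wavelet-tree ranks — O(log sigma) total — while the space drops
to O(n log(sigma) / sqrt(l)) bits for average run length ``l``.

Block-size selection follows the accounted size
``S(b) = m + A*(|T_R| + |T_P|)`` bits (``A`` bits per stored character):
powers of two are scanned, then the analytic bound
``b* = ceil(sqrt((1 + A*n) / (A*r)))`` and ``floor(3*b_hat/2)`` are also
inspected, and the smallest size attaining the minimum wins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil, sqrt

import numpy as np

from .bitvector import RankBitVector
from .wavelet import WaveletTree

#: sizes are searched over powers of two starting at 4, capped here
MAX_BLOCK_SIZE = 1 << 20


def _to_codes(seq, alphabet):
    if isinstance(seq, np.ndarray) and seq.dtype.kind in "iu":
        codes = seq.astype(np.int64)
        if alphabet is None:
            alphabet = tuple(range(int(codes.max()) + 1 if codes.size else 1))
        return codes, tuple(alphabet)
    if alphabet is None:
        alphabet = tuple(sorted(set(seq)))
    code_of = {s: i for i, s in enumerate(alphabet)}
    codes = np.fromiter((code_of[s] for s in seq), dtype=np.int64, count=len(seq))
    return codes, tuple(alphabet)


def count_runs(seq) -> int:
    """Number of maximal single-character runs in ``seq``."""
    codes, _ = _to_codes(seq, None)
    if codes.size == 0:
        return 0
    return int(np.count_nonzero(codes[1:] != codes[:-1])) + 1


def _block_split(codes: np.ndarray, b: int):
    """Return (is_run per block, run chars, plain chars)."""
    n = codes.size
    m = ceil(n / b)
    n_full = n // b
    full = codes[: n_full * b].reshape(n_full, b)
    is_run_full = (full == full[:, :1]).all(axis=1)
    is_run = np.zeros(m, dtype=bool)
    is_run[:n_full] = is_run_full
    tail = codes[n_full * b :]
    if tail.size:
        is_run[-1] = bool((tail == tail[0]).all())
    run_chars = []
    plain_parts = []
    if n_full:
        run_chars.append(full[is_run_full, 0])
        plain_parts = [full[~is_run_full].reshape(-1)]
    if tail.size:
        if is_run[-1]:
            run_chars.append(tail[:1])
        else:
            plain_parts.append(tail)
    t_r = np.concatenate(run_chars) if run_chars else np.empty(0, dtype=np.int64)
    t_p = np.concatenate(plain_parts) if plain_parts else np.empty(0, dtype=np.int64)
    return is_run, t_r, t_p


class RunBlockSequence:
    """Block-partitioned compressed text with O(log sigma) rank."""

    __slots__ = ("n", "b", "m", "alphabet", "B_R", "T_R", "T_P")

    def __init__(self, seq, b: int, alphabet=None) -> None:
        if b < 2:
            raise ValueError(f"block size must be >= 2, got {b}")
        codes, alphabet = _to_codes(seq, alphabet)
        if codes.size == 0:
            raise ValueError("cannot compress an empty sequence")
        self.n = int(codes.size)
        self.b = int(b)
        self.m = ceil(self.n / b)
        self.alphabet = alphabet
        is_run, t_r, t_p = _block_split(codes, b)
        self.B_R = RankBitVector(is_run.astype(np.uint8))
        self.T_R = WaveletTree(t_r, alphabet)
        self.T_P = WaveletTree(t_p, alphabet)

    def __len__(self) -> int:
        return self.n

    @property
    def stored_characters(self) -> int:
        """Characters kept across both subsequences (|T_R| + |T_P|)."""
        return self.T_R.n + self.T_P.n

    def rank(self, c, i: int) -> int:
        """Occurrences of ``c`` in the first ``i`` characters of the text.

        Two cases depending on whether position ``i`` falls in a run
        block: run blocks contribute ``b`` characters each through
        ``T_R`` with a correction term for the current partial block
        (whose indicator comes for free from the rank-with-match query);
        non-run blocks are counted directly inside ``T_P``.
        """
        if i == 0:
            return 0
        if i < 0 or i > self.n:
            raise IndexError(f"position {i} out of range [0, {self.n}]")
        b = self.b
        k = (i + b - 1) // b
        r_r = self.B_R.rank1(k)
        rbar = k - r_r
        off = (i - 1) % b + 1
        if self.B_R.get(k):
            cnt, matched = self.T_R.rank_with_match(c, r_r)
            total = b * cnt + self.T_P.rank(c, rbar * b)
            if matched:
                total += off - b
            return total
        return b * self.T_R.rank(c, r_r) + self.T_P.rank(c, (rbar - 1) * b + off)

    def access(self, i: int):
        """Character at 1-based position ``i`` of the original text."""
        if i < 1 or i > self.n:
            raise IndexError(f"position {i} out of range [1, {self.n}]")
        b = self.b
        k = (i + b - 1) // b
        r_r = self.B_R.rank1(k)
        if self.B_R.get(k):
            return self.T_R.access(r_r)
        rbar = k - r_r
        return self.T_P.access((rbar - 1) * b + (i - 1) % b + 1)

    def decompress(self) -> list:
        return [self.access(i) for i in range(1, self.n + 1)]

    # -- serialization -------------------------------------------------
    def state(self) -> dict:
        return {
            "n": self.n,
            "b": self.b,
            "alphabet": list(self.alphabet),
            "B_R": self.B_R.state(),
            "T_R": self.T_R.state(),
            "T_P": self.T_P.state(),
        }

    @classmethod
    def from_state(cls, state: dict) -> "RunBlockSequence":
        rb = cls.__new__(cls)
        rb.n = int(state["n"])
        rb.b = int(state["b"])
        rb.m = ceil(rb.n / rb.b)
        rb.alphabet = tuple(state["alphabet"])
        rb.B_R = RankBitVector.from_state(state["B_R"])
        rb.T_R = WaveletTree.from_state(state["T_R"])
        rb.T_P = WaveletTree.from_state(state["T_P"])
        return rb


def rb_compress(seq, b: int, alphabet=None) -> RunBlockSequence:
    """Compress ``seq`` with block size ``b``."""
    return RunBlockSequence(seq, b, alphabet=alphabet)


@dataclass
class BlockSizeReport:
    """Outcome of the block-size search."""

    candidate_sizes: list[int]
    space_bits: dict[int, int]
    chosen: int
    b_star: int
    A: int
    r: int
    n: int = 0
    extras: list[int] = field(default_factory=list)


def accounted_bits(seq, b: int, A: int) -> int:
    """Accounted size S(b) in bits: |B_R| + A*(|T_R| + |T_P|)."""
    codes, _ = _to_codes(seq, None)
    m = ceil(codes.size / b)
    is_run, t_r, t_p = _block_split(codes, b)
    return m + A * (t_r.size + t_p.size)


def choose_block_size(prefix, A: int, max_block: int = MAX_BLOCK_SIZE) -> BlockSizeReport:
    """Pick the block size minimizing the accounted size S(b).

    ``prefix`` should be (a prefix of) the sequence to compress — the
    index builder passes the first million BWT characters. Powers of two
    from 4 up to ``min(n, max_block)`` are scanned; the analytic bound
    b* and floor(3/2 of the best power of two) are then also evaluated.
    Ties go to the smaller size.
    """
    codes, _ = _to_codes(prefix, None)
    n = int(codes.size)
    if n == 0:
        raise ValueError("cannot select a block size from an empty prefix")
    r = count_runs(codes)
    candidates = []
    b = 4
    while b <= min(n, max_block):
        candidates.append(b)
        b *= 2
    if not candidates:
        candidates = [2]
    space = {b: accounted_bits(codes, b, A) for b in candidates}
    b_hat = min(candidates, key=lambda b: (space[b], b))
    b_star = max(2, ceil(sqrt((1 + A * n) / (A * r))))
    extras = [b_star, max(2, (3 * b_hat) // 2)]
    for b in extras:
        if b not in space:
            space[b] = accounted_bits(codes, b, A)
    chosen = min(space, key=lambda b: (space[b], b))
    return BlockSizeReport(
        candidate_sizes=candidates,
        space_bits=space,
        chosen=chosen,
        b_star=b_star,
        A=A,
        r=r,
        n=n,
        extras=extras,
    )
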