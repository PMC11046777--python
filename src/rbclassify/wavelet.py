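"""Balanced wavelet trees over small alphabets.

The tree is pointerless: all nodes of one depth share a single
:class:`~rbclassify.bitvector.RankBitVector`, and node boundaries within
each level are precomputed at construction. Characters receive
consecutive integer codes in alphabet order and the tree splits on code
bits from most to least significant, giving a balanced binary shape with
``ceil(log2 sigma)`` levels. Rank, access, and the combined
rank-with-match query all cost one bit-vector operation per level.
"""

from __future__ import annotations

from typing import Hashable, Sequence

import numpy as np

from .bitvector import RankBitVector


def _as_codes(seq, code_of: dict) -> np.ndarray:
    if isinstance(seq, np.ndarray) and seq.dtype.kind in "iu":
        return seq.astype(np.int64)
    return np.fromiter((code_of[s] for s in seq), dtype=np.int64, count=len(seq))


class WaveletTree:
    """Rank/access structure for a static sequence over a fixed alphabet."""

    __slots__ = ("alphabet", "_code", "width", "n", "levels", "_starts", "_zeros_before")

    def __init__(self, seq, alphabet: Sequence[Hashable]) -> None:
        self.alphabet = tuple(alphabet)
        sigma = len(self.alphabet)
        if sigma == 0:
            raise ValueError("alphabet must be non-empty")
        self._code = {s: i for i, s in enumerate(self.alphabet)}
        if len(self._code) != sigma:
            raise ValueError("alphabet contains duplicates")
        self.width = max(1, int(np.ceil(np.log2(sigma)))) if sigma > 1 else 1
        codes = _as_codes(seq, self._code)
        if codes.size and (codes.min() < 0 or codes.max() >= sigma):
            raise ValueError("sequence contains symbols outside the alphabet")
        self.n = int(codes.size)
        self.levels = []
        self._starts = []
        self._zeros_before = []
        for t in range(self.width):
            prefix = codes >> (self.width - t)
            order = np.argsort(prefix, kind="stable")
            bits = (codes[order] >> (self.width - 1 - t)) & 1
            bv = RankBitVector(bits)
            starts = np.searchsorted(np.sort(prefix), np.arange(1 << t))
            zcum = np.concatenate(([0], np.cumsum(bits == 0)))
            self.levels.append(bv)
            self._starts.append(starts.astype(np.int64))
            self._zeros_before.append(zcum[starts].astype(np.int64))

    def __len__(self) -> int:
        return self.n

    def _check(self, c, i: int, lo: int = 0) -> int:
        if c not in self._code:
            raise KeyError(f"symbol {c!r} not in alphabet")
        if i < lo or i > self.n:
            raise IndexError(f"position {i} out of range [{lo}, {self.n}]")
        return self._code[c]

    def rank(self, c, i: int) -> int:
        """Occurrences of symbol ``c`` in the first ``i`` positions."""
        code = self._check(c, i)
        pos = i
        node = 0
        w = self.width
        for t in range(w):
            lv = self.levels[t]
            lo = int(self._starts[t][node])
            z = (lo + pos) - lv.rank1(lo + pos) - int(self._zeros_before[t][node])
            bit = (code >> (w - 1 - t)) & 1
            pos = z if bit == 0 else pos - z
            if pos == 0:
                return 0
            node = (node << 1) | bit
        return pos

    def rank_with_match(self, c, i: int) -> tuple[int, bool]:
        """Rank of ``c`` at ``i`` plus whether position ``i`` holds ``c``.

        The match flag is read off the root-to-leaf path followed by the
        rank query itself: while the element at position ``i`` has agreed
        with every code bit of ``c`` so far, it occupies the same child
        slot as the running rank count, so one extra bit probe per level
        decides the flag without a separate access query.
        """
        code = self._check(c, i, lo=1)
        pos = i
        node = 0
        matched = True
        w = self.width
        for t in range(w):
            lv = self.levels[t]
            lo = int(self._starts[t][node])
            bit = (code >> (w - 1 - t)) & 1
            if matched and lv.get(lo + pos) != bit:
                matched = False
            z = (lo + pos) - lv.rank1(lo + pos) - int(self._zeros_before[t][node])
            pos = z if bit == 0 else pos - z
            if pos == 0:
                return 0, False
            node = (node << 1) | bit
        return pos, matched

    def access(self, i: int) -> Hashable:
        """Symbol at 1-based position ``i``."""
        if i < 1 or i > self.n:
            raise IndexError(f"position {i} out of range [1, {self.n}]")
        pos = i
        node = 0
        code = 0
        for t in range(self.width):
            lv = self.levels[t]
            lo = int(self._starts[t][node])
            bit = lv.get(lo + pos)
            z = (lo + pos) - lv.rank1(lo + pos) - int(self._zeros_before[t][node])
            pos = z if bit == 0 else pos - z
            node = (node << 1) | bit
            code = (code << 1) | bit
        return self.alphabet[code]

    def decode(self) -> list:
        return [self.access(i) for i in range(1, self.n + 1)]

    # -- serialization -------------------------------------------------
    def state(self) -> dict:
        return {
            "alphabet": list(self.alphabet),
            "n": self.n,
            "levels": [lv.state() for lv in self.levels],
        }

    @classmethod
    def from_state(cls, state: dict) -> "WaveletTree":
        wt = cls.__new__(cls)
        wt.alphabet = tuple(state["alphabet"])
        wt._code = {s: i for i, s in enumerate(wt.alphabet)}
        sigma = len(wt.alphabet)
        wt.width = max(1, int(np.ceil(np.log2(sigma)))) if sigma > 1 else 1
        wt.n = int(state["n"])
        wt.levels = [RankBitVector.from_state(s) for s in state["levels"]]
        wt._starts = []
        wt._zeros_before = []
        # rebuild node boundaries by replaying the level bit vectors
        starts = np.zeros(1, dtype=np.int64)
        sizes = np.array([wt.n], dtype=np.int64)
        for t in range(wt.width):
            lv = wt.levels[t]
            zcum_starts = np.array([lv.rank0(int(s)) for s in starts], dtype=np.int64)
            wt._starts.append(starts)
            wt._zeros_before.append(zcum_starts)
            ends = starts + sizes
            zeros = np.array(
                [lv.rank0(int(e)) - lv.rank0(int(s)) for s, e in zip(starts, ends)],
                dtype=np.int64,
            )
            new_starts = np.empty(2 * starts.size, dtype=np.int64)
            new_sizes = np.empty(2 * starts.size, dtype=np.int64)
            new_starts[0::2] = starts
            new_sizes[0::2] = zeros
            new_starts[1::2] = starts + zeros
            new_sizes[1::2] = sizes - zeros
            starts, sizes = new_starts, new_sizes
        return wt
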