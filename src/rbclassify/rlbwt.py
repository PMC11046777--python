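"""Run-length and hybrid run-length compressed sequences.

``RunLengthSequence`` is a classic run-length BWT representation: one
character per run in a wavelet tree, run heads marked in a bit vector
over the original positions, and per-character run lengths kept in
unary-coded bit vectors so that prefix sums of run lengths come from
rank/select on bit vectors instead of stored integer arrays.

``HybridRLSequence`` cuts the text into fixed-size blocks like the
run-block scheme, but marks a block compressible when its *average run
length exceeds six* (runs counted within the block, boundaries resetting
runs). Compressible blocks concatenate into a run-length coded
subsequence, the rest into a plain wavelet tree; rank combines the two
exactly as in the run-block decomposition. When nothing is compressible
the stored payload equals the plain wavelet tree; when everything is,
it converges to the run-length BWT.
"""

from __future__ import annotations

from math import ceil

import numpy as np

from .bitvector import RankBitVector
from .runblock import _to_codes
from .wavelet import WaveletTree

#: a block is run-length compressible when block_len / runs > this
AVG_RUN_THRESHOLD = 6.0


class RunLengthSequence:
    """Run-length coded sequence with rank and access."""

    __slots__ = ("n", "alphabet", "run_chars", "run_starts", "_unary")

    def __init__(self, seq, alphabet=None) -> None:
        codes, alphabet = _to_codes(seq, alphabet)
        self.n = int(codes.size)
        self.alphabet = alphabet
        if self.n:
            heads = np.concatenate(([True], codes[1:] != codes[:-1]))
        else:
            heads = np.zeros(0, dtype=bool)
        starts = np.flatnonzero(heads)
        chars = codes[starts]
        lengths = np.diff(np.concatenate((starts, [self.n])))
        self.run_chars = WaveletTree(chars, alphabet)
        self.run_starts = RankBitVector(heads.astype(np.uint8))
        # per-character unary run-length coding: for character c, a bit
        # vector over the concatenation of all c-runs with a 1 at each
        # run's first position; prefix sums of c-run lengths are then
        # select queries on this vector
        self._unary = []
        for c in range(len(alphabet)):
            sel = chars == c
            lens_c = lengths[sel]
            total = int(lens_c.sum())
            bits = np.zeros(total, dtype=np.uint8)
            if lens_c.size:
                bits[np.concatenate(([0], np.cumsum(lens_c[:-1])))] = 1
            self._unary.append(RankBitVector(bits))

    def __len__(self) -> int:
        return self.n

    @property
    def n_runs(self) -> int:
        return self.run_chars.n

    def _cum_len(self, code: int, k: int) -> int:
        """Total length of the first ``k`` runs of character ``code``."""
        u = self._unary[code]
        if k <= 0:
            return 0
        if k >= u.count1:
            return u.nbits
        return u.select1(k + 1) - 1

    def rank(self, c, i: int) -> int:
        if i == 0:
            return 0
        if i < 0 or i > self.n:
            raise IndexError(f"position {i} out of range [0, {self.n}]")
        code = self.run_chars._code[c] if not isinstance(c, (int, np.integer)) else int(c)
        sym = self.alphabet[code]
        j = self.run_starts.rank1(i)
        cnt, is_c = self.run_chars.rank_with_match(sym, j)
        full = cnt - 1 if is_c else cnt
        total = self._cum_len(code, full)
        if is_c:
            total += i - self.run_starts.select1(j) + 1
        return total

    def access(self, i: int):
        if i < 1 or i > self.n:
            raise IndexError(f"position {i} out of range [1, {self.n}]")
        return self.run_chars.access(self.run_starts.rank1(i))

    def decompress(self) -> list:
        return [self.access(i) for i in range(1, self.n + 1)]

    # -- serialization -------------------------------------------------
    def state(self) -> dict:
        return {
            "n": self.n,
            "alphabet": list(self.alphabet),
            "run_chars": self.run_chars.state(),
            "run_starts": self.run_starts.state(),
            "unary": [u.state() for u in self._unary],
        }

    @classmethod
    def from_state(cls, state: dict) -> "RunLengthSequence":
        rl = cls.__new__(cls)
        rl.n = int(state["n"])
        rl.alphabet = tuple(state["alphabet"])
        rl.run_chars = WaveletTree.from_state(state["run_chars"])
        rl.run_starts = RankBitVector.from_state(state["run_starts"])
        rl._unary = [RankBitVector.from_state(s) for s in state["unary"]]
        return rl


def _runs_per_block(codes: np.ndarray, b: int) -> np.ndarray:
    """Run counts of each block, block boundaries resetting runs."""
    n = codes.size
    m = ceil(n / b)
    heads = np.ones(n, dtype=np.int64)
    same = codes[1:] == codes[:-1]
    # a position is a new run unless it continues the previous character
    # within the same block
    cont = np.flatnonzero(same) + 1
    cont = cont[cont % b != 0]
    heads[cont] = 0
    block_of = np.arange(n) // b
    return np.bincount(block_of, weights=heads, minlength=m).astype(np.int64)


class HybridRLSequence:
    """Per-block hybrid of run-length coding and plain wavelet storage."""

    __slots__ = ("n", "b", "m", "alphabet", "B_R", "T_R", "T_P", "threshold")

    def __init__(self, seq, b: int, alphabet=None, threshold: float = AVG_RUN_THRESHOLD) -> None:
        if b < 2:
            raise ValueError(f"block size must be >= 2, got {b}")
        codes, alphabet = _to_codes(seq, alphabet)
        if codes.size == 0:
            raise ValueError("cannot compress an empty sequence")
        self.n = int(codes.size)
        self.b = int(b)
        self.m = ceil(self.n / b)
        self.alphabet = alphabet
        self.threshold = float(threshold)
        runs = _runs_per_block(codes, b)
        block_len = np.full(self.m, b, dtype=np.int64)
        block_len[-1] = self.n - (self.m - 1) * b
        compressible = block_len / runs > self.threshold
        self.B_R = RankBitVector(compressible.astype(np.uint8))
        block_of = np.arange(self.n) // b
        mask = compressible[block_of]
        self.T_R = RunLengthSequence(codes[mask], alphabet)
        self.T_P = WaveletTree(codes[~mask], alphabet)

    def __len__(self) -> int:
        return self.n

    @property
    def stored_characters(self) -> int:
        return self.T_R.n + self.T_P.n

    def rank(self, c, i: int) -> int:
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
            return self.T_R.rank(c, (r_r - 1) * b + off) + self.T_P.rank(c, rbar * b)
        return self.T_R.rank(c, r_r * b) + self.T_P.rank(c, (rbar - 1) * b + off)

    def access(self, i: int):
        if i < 1 or i > self.n:
            raise IndexError(f"position {i} out of range [1, {self.n}]")
        b = self.b
        k = (i + b - 1) // b
        r_r = self.B_R.rank1(k)
        off = (i - 1) % b + 1
        if self.B_R.get(k):
            return self.T_R.access((r_r - 1) * b + off)
        rbar = k - r_r
        return self.T_P.access((rbar - 1) * b + off)

    def decompress(self) -> list:
        return [self.access(i) for i in range(1, self.n + 1)]

    # -- serialization -------------------------------------------------
    def state(self) -> dict:
        return {
            "n": self.n,
            "b": self.b,
            "threshold": self.threshold,
            "alphabet": list(self.alphabet),
            "B_R": self.B_R.state(),
            "T_R": self.T_R.state(),
            "T_P": self.T_P.state(),
        }

    @classmethod
    def from_state(cls, state: dict) -> "HybridRLSequence":
        h = cls.__new__(cls)
        h.n = int(state["n"])
        h.b = int(state["b"])
        h.m = ceil(h.n / h.b)
        h.threshold = float(state["threshold"])
        h.alphabet = tuple(state["alphabet"])
        h.B_R = RankBitVector.from_state(state["B_R"])
        h.T_R = RunLengthSequence.from_state(state["T_R"])
        h.T_P = WaveletTree.from_state(state["T_P"])
        return h


def hybrid_compress(seq, b: int, alphabet=None, threshold: float = AVG_RUN_THRESHOLD) -> HybridRLSequence:
    return HybridRLSequence(seq, b, alphabet=alphabet, threshold=threshold)
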