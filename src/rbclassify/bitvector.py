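"""Bit vectors with constant-time rank.

The rank directory stores one cumulative popcount per packed byte, so a
rank query is one table lookup plus a masked popcount of a single byte.
All public positions are 1-based, matching the rank convention used by
the compressed-sequence formulas elsewhere in the package; ``rank(i)``
counts bits in the prefix of length ``i`` (``i = 0`` is the empty
prefix).
"""

from __future__ import annotations

import numpy as np

# _PREFIX_POP[byte, r] = popcount of the r most significant bits of byte
_PREFIX_POP = np.zeros((256, 9), dtype=np.uint8)
for _byte in range(256):
    for _r in range(9):
        _PREFIX_POP[_byte, _r] = bin(_byte >> (8 - _r)).count("1")


class RankBitVector:
    """Static bit vector supporting O(1) rank and O(log m) select."""

    __slots__ = ("nbits", "_bytes", "_cum")

    def __init__(self, bits) -> None:
        bits = np.asarray(bits, dtype=np.uint8)
        if bits.ndim != 1:
            raise ValueError("bits must be one-dimensional")
        self.nbits = int(bits.size)
        self._bytes = np.packbits(bits)
        counts = np.bitwise_count(self._bytes).astype(np.int64)
        self._cum = np.concatenate(([0], np.cumsum(counts)))

    def __len__(self) -> int:
        return self.nbits

    @property
    def count1(self) -> int:
        """Total number of set bits."""
        return int(self._cum[-1])

    def rank1(self, i: int) -> int:
        """Number of 1-bits among the first ``i`` positions."""
        if i < 0 or i > self.nbits:
            raise IndexError(f"rank position {i} out of range [0, {self.nbits}]")
        q, r = divmod(i, 8)
        c = int(self._cum[q])
        if r:
            c += int(_PREFIX_POP[self._bytes[q], r])
        return c

    def rank0(self, i: int) -> int:
        """Number of 0-bits among the first ``i`` positions."""
        return i - self.rank1(i)

    def rank(self, bit: int, i: int) -> int:
        return self.rank1(i) if bit else self.rank0(i)

    def get(self, i: int) -> int:
        """Bit at 1-based position ``i``."""
        if i < 1 or i > self.nbits:
            raise IndexError(f"position {i} out of range [1, {self.nbits}]")
        q, r = divmod(i - 1, 8)
        return (int(self._bytes[q]) >> (7 - r)) & 1

    def select1(self, k: int) -> int:
        """1-based position of the k-th set bit (k >= 1).

        Binary search over the rank directory; no dedicated select
        structure is kept.
        """
        if k < 1 or k > self.count1:
            raise IndexError(f"select index {k} out of range [1, {self.count1}]")
        q = int(np.searchsorted(self._cum, k, side="left")) - 1
        # k-th set bit lies inside byte q
        need = k - int(self._cum[q])
        byte = int(self._bytes[q])
        for r in range(1, 9):
            if (byte >> (8 - r)) & 1:
                need -= 1
                if need == 0:
                    return q * 8 + r
        raise AssertionError("corrupt rank directory")

    def to_array(self) -> np.ndarray:
        return np.unpackbits(self._bytes, count=self.nbits)

    # -- serialization -------------------------------------------------
    def state(self) -> dict:
        return {"nbits": self.nbits, "bytes": self._bytes}

    @classmethod
    def from_state(cls, state: dict) -> "RankBitVector":
        bv = cls.__new__(cls)
        bv.nbits = int(state["nbits"])
        bv._bytes = np.asarray(state["bytes"], dtype=np.uint8)
        counts = np.bitwise_count(bv._bytes).astype(np.int64)
        bv._cum = np.concatenate(([0], np.cumsum(counts)))
        return bv
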