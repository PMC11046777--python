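"""FM-index construction over a concatenated genome database.

The database text is the concatenation of all reference sequences, each
followed by one sentinel character that sorts before every base. The
index keeps the BWT in one of four interchangeable representations
(plain wavelet tree, run-block compressed, hybrid run-length, or
run-length coded), the first-column cumulative counts, and a bit-compact
array of sequence IDs sampled every ``sample_rate``-th BWT row. Genome
offsets are not sampled: classification only ever needs the owning
sequence, which an LF walk to the nearest sampled row recovers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import ceil, log2

import numpy as np

from . import container
from .rlbwt import HybridRLSequence, RunLengthSequence
from .runblock import RunBlockSequence, choose_block_size
from .suffix import bwt_from_sa, suffix_array
from .wavelet import WaveletTree

logger = logging.getLogger(__name__)

SENTINEL = "$"
ALPHABET = (SENTINEL, "A", "C", "G", "T")
_CODE = {c: i for i, c in enumerate(ALPHABET)}
_CODE_ALPHABET = tuple(range(len(ALPHABET)))  # representations work on codes
CODE_WIDTH = max(1, ceil(log2(len(ALPHABET))))

_COMP = str.maketrans("ACGTN", "TGCAN")

REPRESENTATIONS = ("rbbwt", "hybrid", "plain", "rle")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def encode(seq: str) -> np.ndarray:
    """Map a read/reference string to integer codes; unknown bases -> -1."""
    out = np.full(len(seq), -1, dtype=np.int64)
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    for sym in "ACGT":
        out[arr == ord(sym)] = _CODE[sym]
    return out


def id_width(n_sequences: int) -> int:
    """Bits needed to distinguish ``n_sequences`` IDs (never zero)."""
    if n_sequences < 1:
        raise ValueError("need at least one sequence")
    return max(1, ceil(log2(n_sequences))) if n_sequences > 1 else 1


@dataclass
class SequenceDatabase:
    """Concatenated reference text plus per-sequence metadata."""

    names: list[str]
    taxids: list[int]
    lengths: list[int]
    text_codes: np.ndarray | None = None
    n_normalized: int = 0

    @property
    def n_sequences(self) -> int:
        return len(self.names)

    @property
    def n(self) -> int:
        """Total text length in characters, sentinels included."""
        return int(sum(self.lengths)) + self.n_sequences

    @property
    def ends(self) -> np.ndarray:
        """Text position of each sequence's sentinel."""
        lens = np.asarray(self.lengths, dtype=np.int64)
        return np.cumsum(lens + 1) - 1

    def owner(self, pos: int) -> int:
        """Index of the sequence owning text position ``pos``.

        A sentinel belongs to the sequence it terminates.
        """
        return int(np.searchsorted(self.ends, pos, side="left"))


def build_text(records, id_map: dict[str, int]) -> SequenceDatabase:
    """Assemble the database text from FASTA records and a taxonomy map.

    ``records`` yields ``(sequence_id, sequence)`` pairs. Records whose
    ID is missing from ``id_map`` are dropped with a warning; non-ACGT
    characters are normalized to 'A' (count logged).
    """
    names: list[str] = []
    taxids: list[int] = []
    lengths: list[int] = []
    parts: list[np.ndarray] = []
    seen: set[str] = set()
    n_normalized = 0
    for seq_id, seq in records:
        if seq_id in seen:
            raise ValueError(f"duplicate sequence ID {seq_id!r}")
        seen.add(seq_id)
        if seq_id not in id_map:
            logger.warning("sequence %s has no taxonomy ID; dropped", seq_id)
            continue
        if not seq:
            raise ValueError(f"sequence {seq_id!r} is empty")
        codes = encode(seq.upper())
        bad = codes < 0
        n_bad = int(bad.sum())
        if n_bad:
            codes[bad] = _CODE["A"]
            n_normalized += n_bad
        names.append(seq_id)
        taxids.append(int(id_map[seq_id]))
        lengths.append(len(seq))
        parts.append(codes)
        parts.append(np.array([_CODE[SENTINEL]], dtype=np.int64))
    if not names:
        raise ValueError("database is empty (no sequences with taxonomy)")
    if n_normalized:
        logger.info("normalized %d non-ACGT characters to 'A'", n_normalized)
    text = np.concatenate(parts)
    return SequenceDatabase(names, taxids, lengths, text_codes=text, n_normalized=n_normalized)


class SampledIDArray:
    """Bit-compact sequence IDs for every ``rate``-th BWT row.

    IDs of width ``w = max(1, ceil(log2 n_sequences))`` bits are packed
    back to back; the total payload is exactly ``w * m_s`` bits.
    """

    __slots__ = ("rate", "width", "count", "_packed")

    def __init__(self, ids, n_sequences: int, rate: int) -> None:
        if rate < 1:
            raise ValueError("sampling rate must be >= 1")
        ids = np.asarray(ids, dtype=np.int64)
        self.rate = int(rate)
        self.width = id_width(n_sequences)
        self.count = int(ids.size)
        shifts = np.arange(self.width - 1, -1, -1)
        bits = ((ids[:, None] >> shifts) & 1).astype(np.uint8).reshape(-1)
        self._packed = np.packbits(bits)

    @property
    def total_bits(self) -> int:
        return self.width * self.count

    def lookup(self, k: int) -> int:
        """ID stored for the k-th sample (0-based)."""
        if k < 0 or k >= self.count:
            raise IndexError(f"sample index {k} out of range [0, {self.count})")
        off = k * self.width
        b0, bit0 = divmod(off, 8)
        nbytes = (bit0 + self.width + 7) // 8
        chunk = self._packed[b0 : b0 + nbytes].tobytes()
        val = int.from_bytes(chunk, "big")
        shift = nbytes * 8 - bit0 - self.width
        return (val >> shift) & ((1 << self.width) - 1)

    def state(self) -> dict:
        return {
            "rate": self.rate,
            "width": self.width,
            "count": self.count,
            "packed": self._packed,
        }

    @classmethod
    def from_state(cls, state: dict) -> "SampledIDArray":
        sa = cls.__new__(cls)
        sa.rate = int(state["rate"])
        sa.width = int(state["width"])
        sa.count = int(state["count"])
        sa._packed = np.asarray(state["packed"], dtype=np.uint8)
        return sa


_REP_CLASSES = {
    "rbbwt": RunBlockSequence,
    "hybrid": HybridRLSequence,
    "plain": WaveletTree,
    "rle": RunLengthSequence,
}


class FMIndex:
    """Backward-searchable compressed index over the database text."""

    def __init__(
        self,
        bwt_rep,
        representation: str,
        first_counts: np.ndarray,
        sampled: SampledIDArray,
        db: SequenceDatabase,
        next_seq_id: np.ndarray,
        sentinel_lf: np.ndarray,
        block_size: int | None,
    ) -> None:
        self.bwt = bwt_rep
        self.representation = representation
        self.C = np.asarray(first_counts, dtype=np.int64)
        self.sampled = sampled
        self.db = db
        self.next_seq_id = np.asarray(next_seq_id, dtype=np.int64)
        self.sentinel_lf = np.asarray(sentinel_lf, dtype=np.int64)
        self.block_size = block_size
        self.n = len(bwt_rep)
        self.alphabet = ALPHABET

    @property
    def sample_rate(self) -> int:
        return self.sampled.rate

    # -- core queries --------------------------------------------------
    def lf(self, p: int) -> int:
        """LF mapping (1-based rows): row of the preceding text position.

        Sentinel rows carry an explicit tiny permutation: with several
        equal sentinels the rank-derived mapping is not consistent with
        the suffix array at the wraparound row, so the correct targets
        (one per sequence) are recorded at build time. This keeps
        LF(p) = row of (SA[p] - 1 mod n) everywhere, making the LF orbit
        a single n-cycle.
        """
        if p < 1 or p > self.n:
            raise IndexError(f"row {p} out of range [1, {self.n}]")
        c = self.bwt.access(p)
        if c == 0:
            return int(self.sentinel_lf[self.bwt.rank(0, p) - 1])
        return int(self.C[c]) + self.bwt.rank(c, p)

    def backward_extend(self, lo: int, hi: int, code: int):
        """Prepend character ``code`` to the pattern of interval [lo, hi].

        Returns the new 1-based interval, or None when empty.
        """
        if code < 0:
            return None
        base = int(self.C[code])
        new_lo = base + self.bwt.rank(code, lo - 1) + 1
        new_hi = base + self.bwt.rank(code, hi)
        if new_lo > new_hi:
            return None
        return new_lo, new_hi

    def backward_search(self, codes) -> tuple[int, int] | None:
        """BWT interval of a pattern (given as codes), or None."""
        interval = (1, self.n)
        for code in reversed(list(codes)):
            interval = self.backward_extend(interval[0], interval[1], int(code))
            if interval is None:
                return None
        return interval

    def count_occurrences(self, pattern: str) -> int:
        interval = self.backward_search(encode(pattern.upper()))
        return 0 if interval is None else interval[1] - interval[0] + 1

    def resolve_sequence_id(self, p: int) -> int:
        """Sequence ID owning the suffix at BWT row ``p`` (1-based).

        Walks LF until a sampled row (0-based row index divisible by the
        sampling rate). A row whose BWT character is the sentinel marks
        the first character of the current sequence; one more LF lands
        in the sentinel block, where the ID of the sequence following
        that terminator is stored, so every walk terminates without
        crossing into a neighboring sequence.
        """
        if p < 1 or p > self.n:
            raise IndexError(f"row {p} out of range [1, {self.n}]")
        rate = self.sampled.rate
        for _ in range(self.n + 1):
            if (p - 1) % rate == 0:
                return self.sampled.lookup((p - 1) // rate)
            c = self.bwt.access(p)
            if c == 0:  # sentinel: crossing to the previous sequence's terminator
                nxt = int(self.sentinel_lf[self.bwt.rank(0, p) - 1])
                return int(self.next_seq_id[nxt - 1])
            p = int(self.C[c]) + self.bwt.rank(c, p)
        raise RuntimeError("LF walk did not terminate; index is corrupt")

    # -- serialization -------------------------------------------------
    def save(self, path) -> None:
        state = {
            "representation": self.representation,
            "block_size": self.block_size,
            "C": self.C,
            "bwt": self.bwt.state(),
            "sampled": self.sampled.state(),
            "next_seq_id": self.next_seq_id,
            "sentinel_lf": self.sentinel_lf,
            "db": {
                "names": self.db.names,
                "taxids": self.db.taxids,
                "lengths": self.db.lengths,
            },
        }
        container.save_state(path, state)

    @classmethod
    def load(cls, path) -> "FMIndex":
        state = container.load_state(path)
        rep = state["representation"]
        if rep not in _REP_CLASSES:
            raise container.ContainerError(f"unknown BWT representation {rep!r}")
        bwt = _REP_CLASSES[rep].from_state(state["bwt"])
        db = SequenceDatabase(
            names=list(state["db"]["names"]),
            taxids=[int(t) for t in state["db"]["taxids"]],
            lengths=[int(x) for x in state["db"]["lengths"]],
        )
        return cls(
            bwt_rep=bwt,
            representation=rep,
            first_counts=state["C"],
            sampled=SampledIDArray.from_state(state["sampled"]),
            db=db,
            next_seq_id=state["next_seq_id"],
            sentinel_lf=state["sentinel_lf"],
            block_size=state["block_size"],
        )


def sample_sequence_ids(sa: np.ndarray, db: SequenceDatabase, rate: int) -> SampledIDArray:
    """Sequence IDs for BWT rows ``p`` with ``p mod rate == 0`` (0-based)."""
    ends = db.ends
    sampled_rows = np.arange(0, sa.size, rate)
    ids = np.searchsorted(ends, sa[sampled_rows], side="left")
    return SampledIDArray(ids, db.n_sequences, rate)


def build_bwt(db: SequenceDatabase) -> tuple[np.ndarray, np.ndarray]:
    """Suffix-sort the database text; returns (bwt codes, suffix array)."""
    if db.text_codes is None:
        raise ValueError("database text was not retained")
    sa = suffix_array(db.text_codes)
    return bwt_from_sa(db.text_codes, sa), sa


def build_index(
    db: SequenceDatabase,
    representation: str = "rbbwt",
    block_size: int | str = "auto",
    sample_rate: int = 16,
    hybrid_threshold: float = 6.0,
    keep_sa: bool = False,
    block_size_prefix: int = 1_000_000,
):
    """Build the searchable index from an assembled database.

    With ``block_size='auto'`` the block size is selected on the first
    million BWT characters by the accounted-space search. Returns the
    index, or ``(index, suffix_array)`` when ``keep_sa`` is true (tests
    use the retained suffix array as ground truth).
    """
    if representation not in REPRESENTATIONS:
        raise ValueError(f"representation must be one of {REPRESENTATIONS}")
    bwt_codes, sa = build_bwt(db)
    counts = np.bincount(bwt_codes, minlength=len(ALPHABET))
    first_counts = np.concatenate(([0], np.cumsum(counts)))
    chosen_b: int | None = None
    if representation in ("rbbwt", "hybrid"):
        if block_size == "auto":
            report = choose_block_size(bwt_codes[:block_size_prefix], A=CODE_WIDTH)
            chosen_b = report.chosen
        else:
            chosen_b = int(block_size)
        if chosen_b < 2:
            raise ValueError(f"block size must be >= 2, got {chosen_b}")
    if representation == "rbbwt":
        rep = RunBlockSequence(bwt_codes, chosen_b, alphabet=_CODE_ALPHABET)
    elif representation == "hybrid":
        rep = HybridRLSequence(bwt_codes, chosen_b, alphabet=_CODE_ALPHABET, threshold=hybrid_threshold)
    elif representation == "rle":
        rep = RunLengthSequence(bwt_codes, alphabet=_CODE_ALPHABET)
    else:
        rep = WaveletTree(bwt_codes, _CODE_ALPHABET)
    sampled = sample_sequence_ids(sa, db, sample_rate)
    nseq = db.n_sequences
    ends = db.ends
    # sentinel-block rows in suffix order; store the ID of the sequence
    # that follows each terminator in the text (wrapping at the end)
    next_pos = (sa[:nseq] + 1) % db.n
    next_ids = np.searchsorted(ends, next_pos, side="left")
    # explicit LF targets for sentinel BWT rows: the k-th sentinel in BWT
    # row order maps to the row of the terminator at SA[p]-1 (mod n)
    term_row_of = {int(sa[q]): q for q in range(nseq)}
    sent_rows = np.flatnonzero(bwt_codes == 0)
    sentinel_lf = np.array(
        [term_row_of[int((sa[p] - 1) % db.n)] + 1 for p in sent_rows], dtype=np.int64
    )
    logger.info(
        "built %s index: n=%d, sequences=%d, block_size=%s, sample_rate=%d, id_width=%d",
        representation, db.n, nseq, chosen_b, sample_rate, sampled.width,
    )
    idx = FMIndex(
        bwt_rep=rep,
        representation=representation,
        first_counts=first_counts,
        sampled=sampled,
        db=SequenceDatabase(db.names, db.taxids, db.lengths),
        next_seq_id=next_ids,
        sentinel_lf=sentinel_lf,
        block_size=chosen_b,
    )
    if keep_sa:
        return idx, sa
    return idx
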