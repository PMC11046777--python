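"""Read classification by semi-maximal exact matching.

A read is scanned right to left on both strands. Backward search
extends the current match until the BWT interval empties; the match is
emitted, the mismatching base is skipped as a putative variant or
sequencing error, and the search restarts. Matches shorter than the
database-dependent random-match floor are discarded; each surviving
match of length ``l`` contributes ``(l - 15)^2`` to its strand, the
lower-scoring strand is dropped (ties keep both), and sequence IDs are
resolved for at most ``40 * report_threshold`` evenly spaced rows of
each match's BWT interval. Per-sequence scores sum over matches; the
arg-max set is reported, reduced to the report threshold through
taxonomy LCAs when needed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import ceil, log

from .index import FMIndex, encode, reverse_complement
from .taxonomy import TaxonomyTree

logger = logging.getLogger(__name__)

FORWARD = "+"
REVERSE = "-"


def min_valid_match_length(n: int, filter_constant: float = 0.01) -> int:
    """Smallest match length l with expected random hits 2n/4^l <= cutoff.

    Shorter matches are likely random and are filtered before scoring.
    """
    if n < 1:
        raise ValueError("database length must be >= 1")
    l = max(1, ceil(log(2 * n / filter_constant, 4)))
    while 2 * n / 4**l > filter_constant:
        l += 1
    while l > 1 and 2 * n / 4 ** (l - 1) <= filter_constant:
        l -= 1
    return l


def score_match(l_m: int, offset: int = 15) -> int:
    """Quadratic match score (l - offset)^2."""
    return (l_m - offset) ** 2


@dataclass(frozen=True)
class Match:
    """A semi-maximal exact match and its BWT interval."""

    length: int
    s: int  # interval start row, 1-based inclusive
    e: int  # interval end row, 1-based inclusive
    strand: str
    read_end: int  # 0-based read position where the match ends (rightmost base)

    @property
    def interval_size(self) -> int:
        return self.e - self.s + 1


@dataclass
class ClassifyParams:
    report_threshold: int = 1
    resolve_cap_factor: int = 40
    score_offset: int = 15
    filter_constant: float = 0.01
    min_match_length: int | None = None  # override; derived from n when None

    @property
    def resolve_cap(self) -> int:
        return self.resolve_cap_factor * self.report_threshold

    def min_length_for(self, n: int) -> int:
        if self.min_match_length is not None:
            return self.min_match_length
        return min_valid_match_length(n, self.filter_constant)


@dataclass
class ClassificationResult:
    read_id: str
    assignments: list[tuple[str, int, int]]  # (sequence label, taxid, score)
    best_score: int
    second_best_score: int
    hit_length: int
    query_length: int

    @property
    def classified(self) -> bool:
        return bool(self.assignments)

    @property
    def n_assignments(self) -> int:
        return len(self.assignments)


def find_semi_maximal_matches(read: str, idx: FMIndex, strand: str = FORWARD) -> list[Match]:
    """All semi-maximal matches of one strand, right to left.

    Unknown bases ('N') never match and act as mismatches: they end the
    current match and are skipped like any other mismatch.
    """
    codes = encode(read.upper())
    n_read = codes.size
    matches: list[Match] = []
    extend = idx.backward_extend
    n = idx.n
    i = n_read - 1
    while i >= 0:
        lo, hi = 1, n
        length = 0
        j = i
        while j >= 0:
            nxt = extend(lo, hi, int(codes[j])) if codes[j] >= 0 else None
            if nxt is None:
                break
            lo, hi = nxt
            length += 1
            j -= 1
        if length > 0:
            matches.append(Match(length, lo, hi, strand, read_end=i))
        i = j - 1  # skip the mismatching base and restart
    return matches


def resolve_positions(s: int, e: int, cap: int) -> list[int]:
    """At most ``cap`` rows evenly spread over [s, e], endpoints included."""
    if e < s:
        raise ValueError(f"empty interval [{s}, {e}]")
    if cap < 1:
        raise ValueError("cap must be >= 1")
    size = e - s + 1
    if size <= cap:
        return list(range(s, e + 1))
    if cap == 1:
        return [s]
    step = (e - s) / (cap - 1)
    out = []
    prev = None
    for j in range(cap):
        p = s + round(j * step)
        if p != prev:
            out.append(p)
            prev = p
    return out


def select_strand(forward, reverse, min_len: int, offset: int = 15):
    """Keep the matches of the higher-scoring strand (ties keep both).

    Inputs are per-strand match lists already found on the index; only
    matches at or above ``min_len`` count. Returns (kept matches,
    forward total, reverse total).
    """
    fwd = [m for m in forward if m.length >= min_len]
    rev = [m for m in reverse if m.length >= min_len]
    f_total = sum(score_match(m.length, offset) for m in fwd)
    r_total = sum(score_match(m.length, offset) for m in rev)
    if f_total > r_total:
        kept = fwd
    elif r_total > f_total:
        kept = rev
    else:
        kept = fwd + rev
    return kept, f_total, r_total


def _score_sequences(matches, idx: FMIndex, params: ClassifyParams) -> dict[int, int]:
    """Per-sequence score totals from a list of kept matches."""
    scores: dict[int, int] = {}
    cap = params.resolve_cap
    for m in matches:
        ids = {idx.resolve_sequence_id(p) for p in resolve_positions(m.s, m.e, cap)}
        inc = score_match(m.length, params.score_offset)
        for sid in ids:
            scores[sid] = scores.get(sid, 0) + inc
    return scores


def classify_read(
    read,
    idx: FMIndex,
    tree: TaxonomyTree,
    params: ClassifyParams | None = None,
    read_id: str = "read",
) -> ClassificationResult:
    """Classify a read (str) or a read pair (tuple of two str).

    For pairs, mate orientations are paired FR-style: mate1-forward with
    mate2-reverse and vice versa, and the better-scoring orientation is
    kept before sequence resolution.
    """
    params = params or ClassifyParams()
    min_len = params.min_length_for(idx.n)
    if isinstance(read, (tuple, list)):
        r1, r2 = read
        query_length = len(r1) + len(r2)
        fwd = find_semi_maximal_matches(r1, idx, FORWARD) + find_semi_maximal_matches(
            reverse_complement(r2), idx, FORWARD
        )
        rev = find_semi_maximal_matches(reverse_complement(r1), idx, REVERSE) + (
            find_semi_maximal_matches(r2, idx, REVERSE)
        )
    else:
        query_length = len(read)
        fwd = find_semi_maximal_matches(read, idx, FORWARD)
        rev = find_semi_maximal_matches(reverse_complement(read), idx, REVERSE)
    kept, f_total, r_total = select_strand(fwd, rev, min_len, params.score_offset)
    if not kept:
        return ClassificationResult(read_id, [], 0, 0, 0, query_length)
    hit_length = sum(m.length for m in kept if m.strand == FORWARD) or sum(
        m.length for m in kept
    )
    scores = _score_sequences(kept, idx, params)
    best = max(scores.values())
    winners = sorted(sid for sid, sc in scores.items() if sc == best)
    others = [sc for sc in scores.values() if sc < best]
    second = max(others) if others else 0
    def safe_tax(t: int) -> int:
        # stale map entries fall back to the root
        if t not in tree:
            logger.warning("taxonomy ID %d not in tree; reporting root", t)
            return tree.root
        return t

    if len(winners) == 1:
        sid = winners[0]
        assignments = [(idx.db.names[sid], safe_tax(idx.db.taxids[sid]), best)]
    else:
        taxids = sorted({safe_tax(idx.db.taxids[sid]) for sid in winners})
        reported = taxids
        if len(taxids) > params.report_threshold:
            reported = sorted(tree.reduce_to_threshold(taxids, params.report_threshold))
        by_tax: dict[int, list[int]] = {}
        for sid in winners:
            by_tax.setdefault(safe_tax(idx.db.taxids[sid]), []).append(sid)
        assignments = []
        for t in reported:
            if t in by_tax and len(by_tax[t]) == 1:
                label = idx.db.names[by_tax[t][0]]
            else:
                label = "merged"
            assignments.append((label, t, best))
    return ClassificationResult(read_id, assignments, best, second, hit_length, query_length)
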