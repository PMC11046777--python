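import numpy as np
import pytest

from rbclassify.classify import (
    ClassifyParams,
    classify_read,
    find_semi_maximal_matches,
    min_valid_match_length,
    resolve_positions,
    score_match,
    select_strand,
)
from rbclassify.index import build_index, build_text, reverse_complement
from rbclassify.synthetic import four_sequence_example
from rbclassify.taxonomy import TaxonomyTree


@pytest.fixture(scope="module")
def fig_example():
    sequences, id_map, nodes, read, expected = four_sequence_example(seed=5)
    db = build_text(sequences, id_map)
    idx = build_index(db)
    tree = TaxonomyTree({t: v[0] for t, v in nodes.items()},
                        {t: v[1] for t, v in nodes.items()})
    return idx, tree, read, expected


def test_min_valid_match_length_values():
    assert min_valid_match_length(140_000_000_000) == 23
    assert min_valid_match_length(int(1.4e11)) == 23
    assert min_valid_match_length(1) == 4
    assert min_valid_match_length(100) == 8


def test_min_valid_match_length_is_minimal():
    for n in (1, 100, 10_000, 140_000_000_000):
        l = min_valid_match_length(n)
        assert 2 * n / 4**l <= 0.01
        assert l == 1 or 2 * n / 4 ** (l - 1) > 0.01


def test_score_is_quadratic_around_offset():
    assert score_match(60) + score_match(39) == 2601
    assert score_match(15) == 0
    assert score_match(16) == 1


def test_resolve_positions_even_spread():
    pos = resolve_positions(100, 490, 40)
    assert pos == list(range(100, 491, 10))
    assert resolve_positions(3, 7, 40) == [3, 4, 5, 6, 7]
    assert resolve_positions(0, 9, 10) == list(range(10))


def test_resolve_positions_stays_inside_interval(rng):
    for _ in range(50):
        s = int(rng.integers(0, 1000))
        e = s + int(rng.integers(0, 2000))
        cap = int(rng.integers(1, 60))
        pos = resolve_positions(s, e, cap)
        assert len(pos) <= cap
        assert pos[0] == s
        assert all(s <= p <= e for p in pos)
        if e - s + 1 > cap and cap > 1:
            assert pos[-1] == e
        assert pos == sorted(set(pos))


def test_two_matches_with_one_mismatched_base(fig_example):
    idx, _, read, expected = fig_example
    matches = find_semi_maximal_matches(read, idx)
    lengths = sorted((m.length for m in matches), reverse=True)
    assert tuple(lengths) == expected["match_lengths"]
    m60 = next(m for m in matches if m.length == 60)
    m39 = next(m for m in matches if m.length == 39)
    assert m60.interval_size == 3  # X, Y, Z
    assert m39.interval_size == 2  # W, X
    assert m60.read_end == 99
    assert m39.read_end == 38


def test_full_read_yields_single_full_length_match(fig_example):
    idx, _, read, _ = fig_example
    seq_x = None
    # a read identical to an indexed substring matches in one piece
    matches = find_semi_maximal_matches(read[40:], idx)
    assert len(matches) == 1
    assert matches[0].length == 60


def test_emitted_matches_occur_exactly_interval_size_times(rng):
    seqs = [(f"s{i}", "".join(rng.choice(list("ACGT"), size=200))) for i in range(3)]
    db = build_text(seqs, {f"s{i}": i + 1 for i in range(3)})
    idx = build_index(db)
    texts = [s for _, s in seqs]
    for _ in range(10):
        read = "".join(rng.choice(list("ACGT"), size=50))
        for m in find_semi_maximal_matches(read, idx):
            sub = read[m.read_end - m.length + 1 : m.read_end + 1]
            naive = sum(
                1
                for t in texts
                for i in range(len(t) - len(sub) + 1)
                if t[i : i + len(sub)] == sub
            )
            assert naive == m.interval_size


def test_strand_selection_prefers_higher_total(fig_example):
    idx, _, read, _ = fig_example
    fwd = find_semi_maximal_matches(read, idx, "+")
    rev = find_semi_maximal_matches(reverse_complement(read), idx, "-")
    kept, f_total, r_total = select_strand(fwd, rev, min_len=9)
    assert f_total == 2601
    assert f_total > r_total
    assert all(m.strand == "+" for m in kept)


def test_strand_tie_keeps_both():
    a = find_semi_maximal_matches.__module__  # keep import form stable
    from rbclassify.classify import Match

    m1 = [Match(30, 1, 1, "+", 29)]
    m2 = [Match(30, 5, 5, "-", 29)]
    kept, f, r = select_strand(m1, m2, min_len=10)
    assert f == r and len(kept) == 2


def test_worked_example_classifies_to_x(fig_example):
    idx, tree, read, expected = fig_example
    res = classify_read(read, idx, tree, read_id="fig")
    assert res.classified
    label, taxid, score = res.assignments[0]
    assert label == expected["winner"]
    assert taxid == expected["taxid"]
    assert score == expected["score"]
    assert res.best_score == 2601
    assert res.second_best_score == 2025  # Y and Z share only the 60-bp match


def test_unmatchable_read_is_unclassified(fig_example):
    idx, tree, _, _ = fig_example
    res = classify_read("N" * 50, idx, tree, read_id="nn")
    assert not res.classified
    assert res.n_assignments == 0


def test_classification_is_deterministic(fig_example):
    idx, tree, read, _ = fig_example
    a = classify_read(read, idx, tree, read_id="r")
    b = classify_read(read, idx, tree, read_id="r")
    assert a == b


def test_reverse_complement_read_gets_same_assignment(fig_example):
    idx, tree, read, expected = fig_example
    res = classify_read(reverse_complement(read), idx, tree, read_id="rc")
    assert res.classified
    assert res.assignments[0][0] == expected["winner"]
    assert res.assignments[0][2] == expected["score"]


def test_identical_strains_collapse_to_lca(rng):
    genome = "".join(rng.choice(list("ACGT"), size=400))
    seqs = [("stA", genome), ("stB", genome)]
    db = build_text(seqs, {"stA": 1000, "stB": 1001})
    idx = build_index(db)
    tree = TaxonomyTree({1: 1, 100: 1, 1000: 100, 1001: 100},
                        {1: "no rank", 100: "species", 1000: "strain", 1001: "strain"})
    read = genome[100:200]
    res = classify_read(read, idx, tree, read_id="shared")
    assert res.assignments == [("merged", 100, res.best_score)]


def test_paired_reads_combine_mate_scores(fig_example):
    idx, tree, read, expected = fig_example
    r1 = read[:50]
    r2 = reverse_complement(read[50:])
    res = classify_read((r1, r2), idx, tree, read_id="pair")
    assert res.classified
    assert res.assignments[0][0] == expected["winner"]
    assert res.query_length == 100


def test_report_threshold_controls_merging(rng):
    genome = "".join(rng.choice(list("ACGT"), size=300))
    seqs = [("a", genome), ("b", genome), ("c", genome)]
    db = build_text(seqs, {"a": 1000, "b": 1001, "c": 1100})
    idx = build_index(db)
    tree = TaxonomyTree(
        {1: 1, 100: 1, 101: 1, 1000: 100, 1001: 100, 1100: 101},
        {1: "no rank", 100: "species", 101: "species",
         1000: "strain", 1001: "strain", 1100: "strain"},
    )
    read = genome[50:150]
    res1 = classify_read(read, idx, tree, read_id="r", params=ClassifyParams(report_threshold=1))
    assert [a[1] for a in res1.assignments] == [1]
    res2 = classify_read(read, idx, tree, read_id="r", params=ClassifyParams(report_threshold=2))
    assert [a[1] for a in res2.assignments] == [100, 1100]
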