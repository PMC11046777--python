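import numpy as np
import pytest

from rbclassify.container import ContainerError
from rbclassify.index import (
    FMIndex,
    SampledIDArray,
    build_index,
    build_text,
    encode,
    id_width,
    sample_sequence_ids,
)
from rbclassify.suffix import bwt_from_sa, inverse_bwt, suffix_array


def _naive_sa(codes):
    n = len(codes)
    return np.array(sorted(range(n), key=lambda i: codes[i:].tolist()), dtype=np.int64)


def test_suffix_array_matches_naive_sort(rng):
    for _ in range(15):
        n = int(rng.integers(2, 200))
        codes = rng.integers(1, 5, size=n).astype(np.int64)
        codes[-1] = 0  # sentinel
        assert np.array_equal(suffix_array(codes), _naive_sa(codes))


def test_suffix_array_with_multiple_sentinels(rng):
    codes = np.array([2, 3, 1, 0, 2, 2, 0, 4, 0], dtype=np.int64)
    assert np.array_equal(suffix_array(codes), _naive_sa(codes))


def test_bwt_of_single_sentinel_text_inverts():
    codes = encode("ACGT")
    text = np.concatenate((codes, [0]))
    sa = suffix_array(text)
    bwt = bwt_from_sa(text, sa)
    assert np.array_equal(inverse_bwt(bwt, first_row=0), text)


def test_bwt_of_repeat_text_has_maximal_run():
    text = np.array([1, 1, 1, 1, 0], dtype=np.int64)  # "AAAA$"
    bwt = bwt_from_sa(text, suffix_array(text))
    # all A's collapse into one run, with the sentinel rotated to the end
    assert bwt.tolist() == [1, 1, 1, 1, 0]


def _toy_db(rng, n_seqs=4, length=150, seed=None):
    from rbclassify.synthetic import BASES

    seqs = []
    for i in range(n_seqs):
        s = "".join(rng.choice(list("ACGT"), size=length))
        seqs.append((f"seq{i}", s))
    id_map = {f"seq{i}": 100 + i for i in range(n_seqs)}
    return build_text(seqs, id_map)


def test_build_text_length_arithmetic():
    db = build_text([("a", "A" * 10), ("b", "C" * 20)], {"a": 1, "b": 2})
    assert db.n == 32  # two sentinels included
    assert db.n_sequences == 2


def test_build_text_drops_records_without_taxonomy(caplog):
    db = build_text([("a", "ACGT"), ("b", "GGGG")], {"a": 5})
    assert db.names == ["a"]


def test_build_text_rejects_duplicates_and_empty():
    with pytest.raises(ValueError):
        build_text([("a", "ACGT"), ("a", "ACGT")], {"a": 1})
    with pytest.raises(ValueError):
        build_text([("a", "ACGT")], {"zzz": 1})


def test_build_text_normalizes_ambiguous_bases():
    db = build_text([("a", "ACNNGT")], {"a": 1})
    assert db.n_normalized == 2
    assert db.text_codes.tolist() == [1, 2, 1, 1, 3, 4, 0]


def test_id_width_cases():
    assert id_width(75865) == 17
    assert id_width(4) == 2
    assert id_width(1) == 1
    assert id_width(2) == 1


def test_sampled_id_array_bit_packing_and_lookup():
    arr = SampledIDArray([3, 0, 2], n_sequences=4, rate=16)
    assert arr.width == 2
    assert arr.total_bits == 6
    assert [arr.lookup(k) for k in range(3)] == [3, 0, 2]
    with pytest.raises(IndexError):
        arr.lookup(3)


def test_sampled_id_array_wide_ids(rng):
    ids = rng.integers(0, 75865, size=40)
    arr = SampledIDArray(ids, n_sequences=75865, rate=16)
    assert arr.width == 17
    assert arr.total_bits == 17 * 40
    assert [arr.lookup(k) for k in range(40)] == ids.tolist()


@pytest.mark.parametrize("rep", ["rbbwt", "hybrid", "plain", "rle"])
def test_backward_search_counts_match_naive(rep, rng):
    db = _toy_db(rng, n_seqs=3, length=120)
    idx = build_index(db, representation=rep, block_size=4 if rep != "plain" else "auto")
    text = "".join({1: "A", 2: "C", 3: "G", 4: "T", 0: "$"}[c] for c in db.text_codes)
    segments = text.split("$")[:-1]
    patterns = set()
    for _ in range(60):
        seg = segments[int(rng.integers(0, len(segments)))]
        k = int(rng.integers(1, 7))
        start = int(rng.integers(0, len(seg) - k + 1))
        patterns.add(seg[start : start + k])
    for _ in range(20):
        patterns.add("".join(rng.choice(list("ACGT"), size=int(rng.integers(1, 7)))))
    for pat in patterns:
        naive = sum(seg.count(pat) for seg in segments)
        # count overlapping occurrences naively
        naive = 0
        for seg in segments:
            naive += sum(1 for i in range(len(seg) - len(pat) + 1) if seg[i : i + len(pat)] == pat)
        assert idx.count_occurrences(pat) == naive, pat


def test_lf_walk_is_single_cycle_and_matches_sa(small_index):
    _, sdb, idx, sa = small_index
    n = idx.n
    p = 1
    seen = 0
    for _ in range(n):
        q = idx.lf(p)
        assert sa[q - 1] == (sa[p - 1] - 1) % n
        p = q
        seen += 1
    assert p == 1 and seen == n


def test_resolution_matches_suffix_array_everywhere(small_index):
    _, sdb, idx, sa = small_index
    owners = np.searchsorted(sdb.ends, sa, side="left")
    for p in range(1, idx.n + 1):
        assert idx.resolve_sequence_id(p) == owners[p - 1]


@pytest.mark.parametrize("rep", ["hybrid", "rle"])
def test_resolution_matches_sa_other_representations(rep, rng):
    db = _toy_db(rng, n_seqs=3, length=100)
    idx, sa = build_index(db, representation=rep, keep_sa=True)
    owners = np.searchsorted(db.ends, sa, side="left")
    for p in range(1, idx.n + 1):
        assert idx.resolve_sequence_id(p) == owners[p - 1]


def test_sampling_anchored_at_rate_multiples(small_index):
    _, sdb, idx, sa = small_index
    owners = np.searchsorted(sdb.ends, sa, side="left")
    rate = idx.sample_rate
    for k in range(idx.sampled.count):
        assert idx.sampled.lookup(k) == owners[k * rate]


def test_serialize_round_trip_preserves_queries(tmp_path, small_index, rng):
    _, sdb, idx, _ = small_index
    path = tmp_path / "toy.rbc"
    idx.save(path)
    idx2 = FMIndex.load(path)
    assert idx2.n == idx.n
    assert idx2.db.names == idx.db.names
    for _ in range(30):
        p = int(rng.integers(1, idx.n + 1))
        assert idx2.lf(p) == idx.lf(p)
        assert idx2.resolve_sequence_id(p) == idx.resolve_sequence_id(p)
    pat = "".join(rng.choice(list("ACGT"), size=5))
    assert idx2.count_occurrences(pat) == idx.count_occurrences(pat)


def test_serialize_rejects_corruption(tmp_path, small_index):
    _, _, idx, _ = small_index
    path = tmp_path / "toy.rbc"
    idx.save(path)
    data = bytearray(path.read_bytes())
    data[:4] = b"XXXX"
    bad = tmp_path / "bad.rbc"
    bad.write_bytes(bytes(data))
    with pytest.raises(ContainerError):
        FMIndex.load(bad)
    trunc = tmp_path / "trunc.rbc"
    trunc.write_bytes(path.read_bytes()[: len(path.read_bytes()) // 2])
    with pytest.raises(ContainerError):
        FMIndex.load(trunc)
    with pytest.raises(ContainerError):
        FMIndex.load(tmp_path / "missing.rbc")
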