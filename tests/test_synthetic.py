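import numpy as np
import pytest

from rbclassify.classify import classify_read
from rbclassify.index import build_index, build_text
from rbclassify.runblock import count_runs
from rbclassify.suffix import bwt_from_sa, suffix_array
from rbclassify.synthetic import (
    SyntheticConfig,
    evaluate,
    generate_database,
    simulate_reads,
    write_database_files,
    write_read_files,
)
from rbclassify.taxonomy import TaxonomyTree


def _tree(db):
    return TaxonomyTree(
        {t: v[0] for t, v in db.taxonomy_nodes.items()},
        {t: v[1] for t, v in db.taxonomy_nodes.items()},
        db.taxonomy_names,
    )


def test_fixed_seed_reproduces_database_and_reads(tmp_path):
    cfg = SyntheticConfig(seed=3, base_genome_length=500, n_species=2, n_strains=2,
                          n_reads=20)
    a = generate_database(cfg)
    b = generate_database(cfg)
    assert a.sequences == b.sequences
    ra, ta = simulate_reads(a, cfg)
    rb, tb = simulate_reads(b, cfg)
    assert ra == rb and ta == tb
    pa = write_database_files(a, tmp_path / "a")
    pb = write_database_files(b, tmp_path / "b")
    assert pa["fasta"].read_bytes() == pb["fasta"].read_bytes()


def test_zero_mutation_rate_gives_identical_strains_and_longer_runs():
    base = dict(base_genome_length=800, n_species=1, n_strains=4)
    same = generate_database(SyntheticConfig(seed=5, mutation_rate=0.0, **base))
    genomes = [s for _, s in same.sequences]
    assert len(set(genomes)) == 1
    diverged = generate_database(SyntheticConfig(seed=5, mutation_rate=0.5, **base))

    def avg_run_length(db):
        sdb = build_text(db.sequences, db.id_map)
        bwt = bwt_from_sa(sdb.text_codes, suffix_array(sdb.text_codes))
        return bwt.size / count_runs(bwt)

    assert avg_run_length(same) > 2 * avg_run_length(diverged)
    assert avg_run_length(diverged) < 3  # near the alphabet baseline


def test_truth_table_matches_read_origin_strain():
    cfg = SyntheticConfig(seed=9, base_genome_length=600, n_species=2, n_strains=2,
                          n_reads=30, error_rate=0.0)
    db = generate_database(cfg)
    reads, truth = simulate_reads(db, cfg)
    genomes = dict(db.sequences)
    comp = str.maketrans("ACGT", "TGCA")
    for rid, seq, _ in reads:
        name, taxid = truth[rid]
        g = genomes[name]
        rc = seq.translate(comp)[::-1]
        assert seq in g or rc in g
        assert db.id_map[name] == taxid


def test_paired_mates_come_from_opposite_strands():
    cfg = SyntheticConfig(seed=2, base_genome_length=800, n_species=1, n_strains=1,
                          n_reads=10, error_rate=0.0, paired=True, insert_size=300)
    db = generate_database(cfg)
    reads, truth = simulate_reads(db, cfg)
    genome = db.sequences[0][1]
    comp = str.maketrans("ACGT", "TGCA")
    for rid, (m1, _), (m2, _) in reads:
        m1_fwd = m1 in genome
        m2_fwd = m2 in genome
        assert m1_fwd != m2_fwd  # exactly one mate on each strand


def test_error_free_unique_reads_classify_perfectly():
    cfg = SyntheticConfig(seed=13, base_genome_length=1500, n_species=2, n_strains=1,
                          n_reads=40, error_rate=0.0, mutation_rate=0.0)
    db = generate_database(cfg)
    sdb = build_text(db.sequences, db.id_map)
    idx = build_index(sdb)
    tree = _tree(db)
    reads, truth = simulate_reads(db, cfg)
    results = [classify_read(seq, idx, tree, read_id=rid) for rid, seq, _ in reads]
    for res in results:
        assert res.classified
        assert res.assignments[0][1] == truth[res.read_id][1]
    metrics = evaluate(results, truth, tree, rank="species")
    assert metrics["sensitivity"] == 1.0
    assert metrics["precision"] == 1.0


def test_read_longer_than_genome_rejected():
    cfg = SyntheticConfig(seed=1, base_genome_length=50, read_length=100,
                          n_species=1, n_strains=1, n_reads=1)
    db = generate_database(cfg)
    with pytest.raises(ValueError):
        simulate_reads(db, cfg)


def test_emitted_files_round_trip(tmp_path):
    cfg = SyntheticConfig(seed=4, base_genome_length=300, n_species=2, n_strains=2,
                          n_reads=8)
    db = generate_database(cfg)
    paths = write_database_files(db, tmp_path)
    reads, truth = simulate_reads(db, cfg)
    paths.update(write_read_files(reads, truth, tmp_path))
    from rbclassify.io import read_fastx, read_seqid_map
    from rbclassify.taxonomy import parse_taxonomy

    fasta = list(read_fastx(paths["fasta"]))
    assert [rid for rid, _, _ in fasta] == [n for n, _ in db.sequences]
    assert [s for _, s, _ in fasta] == [s for _, s in db.sequences]
    assert read_seqid_map(paths["map"]) == db.id_map
    tree = parse_taxonomy(paths["nodes"], paths["names"])
    assert len(tree) == len(db.taxonomy_nodes)
    fastq = list(read_fastx(paths["fastq"]))
    assert len(fastq) == 8
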