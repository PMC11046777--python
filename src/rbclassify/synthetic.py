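"""Synthetic databases and reads with known ground truth.

The generator emulates a small strain-level reference database: each
species gets an independent uniform-random genome, and its strains are
point-mutated copies. The per-strain mutation rate controls how
repetitive the concatenated BWT is (identical strains drive the average
run length up; heavily mutated strains fall back to the ~alphabet-size
baseline), which is the axis the compressed representations care about.
Reads are drawn uniformly from the strain genomes on either strand with
independent substitution errors; a truth table records each read's
origin so sensitivity and precision can be measured at any rank. All
randomness flows from the single seed in the config.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

ROOT_TAXID = 1
DOMAIN_TAXID = 2
BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SyntheticConfig:
    seed: int = 0
    base_genome_length: int = 10_000
    n_species: int = 4
    n_strains: int = 5
    mutation_rate: float = 0.01
    read_length: int = 100
    n_reads: int = 10_000
    error_rate: float = 0.005
    paired: bool = False
    insert_size: int = 300


def species_taxid(s: int) -> int:
    return 100 + s


def strain_taxid(s: int, t: int) -> int:
    return 1000 + 100 * s + t


def strain_name(s: int, t: int) -> str:
    return f"sp{s}_strain{t}"


@dataclass
class SyntheticDatabase:
    config: SyntheticConfig
    sequences: list[tuple[str, str]]  # (sequence id, genome)
    id_map: dict[str, int]  # sequence id -> taxonomy id
    taxonomy_nodes: dict[int, tuple[int, str]]  # taxid -> (parent, rank)
    taxonomy_names: dict[int, str]

    def genome(self, name: str) -> str:
        return dict(self.sequences)[name]


def _mutate(codes: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each position with probability ``rate`` (never silently)."""
    out = codes.copy()
    sites = np.flatnonzero(rng.random(codes.size) < rate)
    if sites.size:
        # draw from the three alternative bases so a mutation always changes
        shift = rng.integers(1, 4, size=sites.size)
        out[sites] = (out[sites] + shift) % 4
    return out


def generate_database(cfg: SyntheticConfig) -> SyntheticDatabase:
    """Build the strain database, taxonomy, and sequence-to-taxid map."""
    rng = np.random.default_rng(cfg.seed)
    sequences: list[tuple[str, str]] = []
    id_map: dict[str, int] = {}
    nodes: dict[int, tuple[int, str]] = {
        ROOT_TAXID: (ROOT_TAXID, "no rank"),
        DOMAIN_TAXID: (ROOT_TAXID, "superkingdom"),
    }
    names: dict[int, str] = {ROOT_TAXID: "root", DOMAIN_TAXID: "Synthetica"}
    for s in range(cfg.n_species):
        base = rng.integers(0, 4, size=cfg.base_genome_length, dtype=np.int64)
        sp = species_taxid(s)
        nodes[sp] = (DOMAIN_TAXID, "species")
        names[sp] = f"Synthetica species{s}"
        for t in range(cfg.n_strains):
            st = strain_taxid(s, t)
            nodes[st] = (sp, "strain")
            names[st] = f"Synthetica species{s} strain {t}"
            genome_codes = _mutate(base, cfg.mutation_rate, rng)
            genome = BASES[genome_codes].tobytes().decode("ascii")
            name = strain_name(s, t)
            sequences.append((name, genome))
            id_map[name] = st
    return SyntheticDatabase(cfg, sequences, id_map, nodes, names)


def simulate_reads(db: SyntheticDatabase, cfg: SyntheticConfig | None = None):
    """Draw reads uniformly from the database with substitution errors.

    Returns ``(reads, truth)``. For single-end configs ``reads`` is a
    list of ``(read_id, sequence, qualities)``; for paired configs each
    item is ``(read_id, (seq1, qual1), (seq2, qual2))`` with mates taken
    from opposite strands at the configured insert size. ``truth`` maps
    read_id -> (sequence id, taxonomy id).
    """
    cfg = cfg or db.config
    rng = np.random.default_rng(cfg.seed + 1)
    genomes = [
        (name, np.frombuffer(seq.encode("ascii"), dtype=np.uint8))
        for name, seq in db.sequences
    ]
    for name, g in genomes:
        span = cfg.insert_size if cfg.paired else cfg.read_length
        if g.size < span:
            raise ValueError(f"sequence {name} shorter than a read/fragment ({span} bp)")
    base_to_code = np.full(256, -1, dtype=np.int64)
    for i, b in enumerate(BASES):
        base_to_code[b] = i
    reads = []
    truth: dict[str, tuple[str, int]] = {}

    def with_errors(sub: np.ndarray) -> str:
        codes = base_to_code[sub]
        err = _mutate(codes, cfg.error_rate, rng)
        return BASES[err].tobytes().decode("ascii")

    def revcomp(seq: str) -> str:
        return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]

    qual = "I" * cfg.read_length
    for i in range(cfg.n_reads):
        gi = int(rng.integers(0, len(genomes)))
        name, g = genomes[gi]
        read_id = f"read{i}|{name}"
        truth[read_id] = (name, db.id_map[name])
        if cfg.paired:
            start = int(rng.integers(0, g.size - cfg.insert_size + 1))
            frag_fwd = rng.integers(0, 2) == 0
            left = with_errors(g[start : start + cfg.read_length])
            right = with_errors(
                g[start + cfg.insert_size - cfg.read_length : start + cfg.insert_size]
            )
            if frag_fwd:
                m1, m2 = left, revcomp(right)
            else:
                m1, m2 = revcomp(right), left
            reads.append((read_id, (m1, qual), (m2, qual)))
        else:
            start = int(rng.integers(0, g.size - cfg.read_length + 1))
            sub = with_errors(g[start : start + cfg.read_length])
            if rng.integers(0, 2) == 1:
                sub = revcomp(sub)
            reads.append((read_id, sub, qual))
    return reads, truth


def four_sequence_example(seed: int = 0):
    """A four-sequence database staging the canonical worked example.

    A 100-bp read matches sequence X everywhere except one substituted
    base 61 positions from its right end, so the right-to-left scan
    finds a 60-bp match (shared with Y and Z, which carry the same
    60-mer), skips the mismatched base, and finds a 39-bp match (shared
    with W, which carries the same 39-mer). X is hit by both matches and
    wins with score (60-15)^2 + (39-15)^2 = 2601.

    Returns (sequences, id_map, taxonomy nodes, read, expected) where
    ``expected`` records the winning sequence and score.
    """
    rng = np.random.default_rng(seed)

    def dna(k):
        return BASES[rng.integers(0, 4, size=k)].tobytes().decode("ascii")

    read = dna(100)
    s60 = read[40:]
    s39 = read[:39]
    mismatch = read[39]
    # every occurrence of the 60-mer must be preceded by a base other
    # than the read's, so the backward extension fails at length 60
    alt = "ACGT"[("ACGT".index(mismatch) + 1) % 4]
    x = s39 + alt + s60
    y = dna(120) + alt + s60 + dna(120)
    z = dna(120) + alt + s60 + dna(120)
    w = dna(120) + s39 + dna(120)
    sequences = [("W", w), ("X", x), ("Y", y), ("Z", z)]
    id_map = {"W": 10, "X": 11, "Y": 12, "Z": 13}
    nodes = {1: (1, "no rank"), 10: (1, "species"), 11: (1, "species"),
             12: (1, "species"), 13: (1, "species")}
    expected = {"winner": "X", "taxid": 11, "score": 2601,
                "match_lengths": (60, 39)}
    return sequences, id_map, nodes, read, expected


# -- file emission -----------------------------------------------------

def write_database_files(db: SyntheticDatabase, outdir) -> dict[str, Path]:
    """Emit FASTA, seq-to-taxid TSV, and taxonomy dump files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fasta = outdir / "genomes.fa"
    with open(fasta, "w") as fh:
        for name, seq in db.sequences:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
    seqmap = outdir / "seqid2taxid.map"
    with open(seqmap, "w") as fh:
        for name, _ in db.sequences:
            fh.write(f"{name}\t{db.id_map[name]}\n")
    nodes = outdir / "nodes.dmp"
    with open(nodes, "w") as fh:
        for taxid in sorted(db.taxonomy_nodes):
            parent, rank = db.taxonomy_nodes[taxid]
            fh.write(f"{taxid}\t|\t{parent}\t|\t{rank}\t|\n")
    names = outdir / "names.dmp"
    with open(names, "w") as fh:
        for taxid in sorted(db.taxonomy_names):
            fh.write(f"{taxid}\t|\t{db.taxonomy_names[taxid]}\t|\t\t|\tscientific name\t|\n")
    return {"fasta": fasta, "map": seqmap, "nodes": nodes, "names": names}


def write_read_files(reads, truth, outdir, paired: bool = False) -> dict[str, Path]:
    """Emit FASTQ (one or two files) plus the truth table TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    out: dict[str, Path] = {}
    if paired:
        p1, p2 = outdir / "reads_1.fq", outdir / "reads_2.fq"
        with open(p1, "w") as f1, open(p2, "w") as f2:
            for read_id, (s1, q1), (s2, q2) in reads:
                f1.write(f"@{read_id}/1\n{s1}\n+\n{q1}\n")
                f2.write(f"@{read_id}/2\n{s2}\n+\n{q2}\n")
        out["fastq1"], out["fastq2"] = p1, p2
    else:
        p = outdir / "reads.fq"
        with open(p, "w") as fh:
            for read_id, seq, q in reads:
                fh.write(f"@{read_id}\n{seq}\n+\n{q}\n")
        out["fastq"] = p
    tpath = outdir / "truth.tsv"
    with open(tpath, "w") as fh:
        fh.write("read_id\tsequence_id\ttaxonomy_id\n")
        for read_id, (name, taxid) in truth.items():
            fh.write(f"{read_id}\t{name}\t{taxid}\n")
    out["truth"] = tpath
    return out


# -- evaluation harness ------------------------------------------------

def evaluate(results, truth, tree, rank: str = "species"):
    """Sensitivity TP/T and precision TP/P at a taxonomy rank.

    A read counts as a true positive when its reported taxonomy ID lies
    at the evaluated node or in its subtree, where the evaluated node is
    the truth taxid's ancestor at ``rank``. A read counts as positive
    when it was classified at or below that rank's depth anywhere.
    """
    def at_rank(taxid: int) -> int | None:
        for t in tree.path_to_root(taxid):
            if tree.rank(t) == rank:
                return t
        return None

    total = 0
    tp = 0
    positive = 0
    for res in results:
        total += 1
        true_seq, true_tax = truth[res.read_id]
        if not res.classified:
            continue
        reported = res.assignments[0][1]
        node = at_rank(true_tax)
        if node is None:
            continue
        rep_node = at_rank(reported)
        if rep_node is not None:
            positive += 1
            if rep_node == node:
                tp += 1
    sens = tp / total if total else 0.0
    prec = tp / positive if positive else 0.0
    return {"sensitivity": sens, "precision": prec, "tp": tp, "t": total, "p": positive}
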