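# rbclassify

Taxonomic classification of metagenomic sequencing reads against a
losslessly compressed FM-index of a microbial genome database.

Classifying reads means comparing each read against every reference
genome, and reference collections now run to hundreds of gigabases, so
the limiting resource is the memory footprint of the index. Many tools
answer this with lossy sketches (minimizers, marker genes, Bloom-style
filters) and pay for it with reduced specificity at low taxonomic
ranks. `rbclassify` keeps the database lossless: the Burrows–Wheeler
transform (BWT) of the concatenated genomes is stored in a **run-block
compressed** form that shrinks with the redundancy of the database
while still answering the rank queries that drive backward search in
O(log σ) time.

## The data structure

The BWT sequence `T` (length `n`, alphabet size σ) is cut into blocks
of `b` characters. A block that is a single repeated character (a *run
block*) is stored as one character in a subsequence `T_R`; every other
block is copied verbatim into `T_P`. A bit vector `B_R` over the `m =
⌈n/b⌉` blocks records which ones were run blocks, and both subsequences
live in balanced wavelet trees. For `rank_c(i, T)` with `k = ⌈i/b⌉`,
`r_r = rank_1(k, B_R)` and `r̄_r = k − r_r`:

- `i` in a run block:
  `rank_c(i,T) = b·rank_c(r_r, T_R) + rank_c(r̄_r·b, T_P) + I[T_R[r_r]=c]·((i−1) mod b + 1 − b)`
- `i` in a non-run block:
  `rank_c(i,T) = b·rank_c(r_r, T_R) + rank_c((r̄_r−1)·b + (i−1) mod b + 1, T_P)`

with the indicator read off the wavelet tree's root-to-leaf path during
the rank query itself. Total space is `O((n/√l)·log σ)` bits, where `l
= n/r` is the average BWT run length, and the block size is selected
automatically by scanning powers of two (plus the analytic optimum
`b* = ⌈√((1+A·n)/(A·r))⌉`) for the smallest accounted size
`S(b) = m + A(|T_R| + |T_P|)`. A hybrid per-block run-length coding
(blocks with average run length > 6 get run-length coded), a plain
wavelet tree, and a classic run-length BWT are available behind the
same interface.

The sampled suffix array stores only *sequence IDs*, not genome
offsets, for every 16th BWT row, bit-packed at
`max(1, ⌈log₂ #sequences⌉)` bits per entry; other rows resolve by LF
walks to the nearest sample.

## Classification

Each read is scanned right to left on both strands. Backward search
extends the current exact match until the BWT interval empties; the
match is emitted, the mismatching base is skipped (a putative variant
or sequencing error), and the search restarts — yielding *semi-maximal
matches*. Matches shorter than the smallest `l` with `2n/4^l ≤ 0.01`
are discarded as likely random. Each surviving match of length `l_M`
adds `(l_M − 15)²` to its strand; the weaker strand is dropped, and
sequence IDs are resolved for at most `40·report_threshold` evenly
spaced rows of each match interval. Per-sequence scores are summed, the
arg-max set is reported, and ties beyond the report threshold collapse
to their lowest common ancestor (LCA) in the taxonomy.

## Worked example

A 100-bp read that differs from database sequence X at a single base 61
positions from its right end splits into a 60-bp match (shared by X, Y,
Z) and, after skipping the mismatch, a 39-bp match (shared by W, X). X
is hit by both, scoring `(60−15)² + (39−15)² = 2025 + 576 = 2601`,
beating Y and Z (2025) and W (576):

```python
from rbclassify import build_index, build_text, classify_read
from rbclassify.synthetic import four_sequence_example
from rbclassify.taxonomy import TaxonomyTree

sequences, id_map, nodes, read, _ = four_sequence_example(seed=5)
idx = build_index(build_text(sequences, id_map))
tree = TaxonomyTree({t: v[0] for t, v in nodes.items()})
res = classify_read(read, idx, tree, read_id="example")
print(res.assignments, res.second_best_score)
# [('X', 11, 2601)] 2025
```

The same pipeline from the shell, on a simulated two-species,
six-strain database:

```
$ rbclassify simulate -o data --seed 4 --species 2 --strains 3 \
      --genome-length 2000 --reads 200 --error-rate 0.005
$ rbclassify build -f data/genomes.fa -m data/seqid2taxid.map -t data -o toy
n=12006 sequences=6 representation=rbbwt block_size=2 sample_rate=16 id_width=3
$ rbclassify classify -x toy -u data/reads.fq -o cls.tsv --report report.tsv
200 reads processed, 200 classified -> cls.tsv
$ head -3 cls.tsv
readID	seqID	taxID	score	2ndBestScore	hitLength	queryLength	numMatches
read0|sp1_strain1	merged	101	1915	1906	98	100	1
read1|sp0_strain0	sp0_strain0	1000	5776	0	91	100	1
```

The first read falls in a region shared by several strains of species
101, so it is merged up to the species node; the second contains
strain-discriminating sites and is assigned uniquely to its strain with
score `(91−15)² = 5776` (91 of its 100 bases matched in one exact
piece). `report.tsv` is a Kraken-style summary whose clade counts sum
over subtrees, usable downstream for abundance estimation.

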