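# Methods

## Database text and alphabet

References are concatenated in input order, each sequence followed by a
single sentinel character that sorts before every base (alphabet
`$ < A < C < G < T`, σ = 5, 3-bit codes). Records without a taxonomy
mapping are dropped with a warning; non-ACGT characters are normalized
to `A` at build time and counted (low-complexity masking is treated as
external preprocessing). Sentinels are one shared character class —
suffixes remain pairwise distinct because they differ in length, so the
suffix order is well defined without per-sequence sentinel symbols.

The suffix array is built by numpy prefix doubling (O(n log² n)), which
is comfortable for the megabase-scale databases this package targets;
the resulting BWT is identical to what any other construction would
give. The BWT row convention is 1-based in every public formula and
0-based in storage; sampling tests `(row − 1) mod rate == 0`.

## Compressed BWT representations

Four interchangeable representations sit behind one `rank`/`access`
interface:

- **run-block** (default): blocks of `b` characters; run blocks stored
  as one character in a wavelet tree `T_R`, the rest verbatim in `T_P`,
  membership in a bit vector `B_R`. Rank follows the two-case
  decomposition described in the README; the indicator "is position i's
  run block a c-block" is inferred during `T_R`'s rank query by
  checking the root-to-leaf path bits against c's code, avoiding a
  separate access.
- **hybrid run-length**: same blocking, but a block is marked
  compressible when its average run length exceeds 6 (strict, runs
  counted within the block so blocks classify independently; the
  threshold is configurable). Compressible blocks concatenate into a
  run-length coded subsequence, the rest into a plain wavelet tree.
  With no compressible blocks the stored payload equals the plain
  wavelet tree; with all blocks compressible it equals the run-length
  BWT.
- **plain wavelet tree** and **run-length BWT** as baselines.

Wavelet trees are balanced and pointerless: one bit vector per level,
characters coded most-significant-bit first, node boundaries
precomputed so rank costs one bit-vector rank per level. Bit vectors
keep one cumulative popcount per packed byte (constant-time rank; any
fixed directory granularity would do). Select — needed only by the
run-length coder's unary run-length vectors — is a binary search over
the rank directory rather than a dedicated structure.

The run-length coder stores one character per run (wavelet tree), run
heads in a bit vector over text positions, and per-character run
lengths as unary-coded bit vectors, so prefix sums of run lengths are
rank/select queries rather than stored integer arrays.

## Block-size selection

The accounted size is `S(b) = m + A(|T_R| + |T_P|)` bits with `A` the
per-character code width (3 for the sentinel-extended DNA alphabet).
Powers of two from 4 to `min(n, 2^20)` are scanned on the first million
BWT characters, then `b* = ⌈√((1+A·n)/(A·r))⌉` (clamped to ≥ 2) and
`⌊3·b̂/2⌋` are also evaluated; the smallest size attaining the minimum
wins. The power-of-two search alone is guaranteed within 3× of `S(b*)`,
which the property suite checks on random texts spanning average run
lengths from ~1 to ~80.

Degenerate inputs: a text with no run of length ≥ 2 makes every block
plain at any `b`, so the chosen size simply minimizes the `B_R`
overhead and the structure reduces to the wavelet-tree representation.
The final short block is classified like any other (run iff all its
characters agree), stored unpadded, and the rank formulas never address
past `n`.

## Sampled sequence IDs and LF walks

Every 16th BWT row (configurable) stores the ID of the sequence owning
the suffix start, packed at `w = max(1, ⌈log₂ #sequences⌉)` bits per
entry with no padding (`w·m_s` bits total; `w` is forced to 1 for a
single-sequence database to avoid zero-width fields). Unsampled rows
resolve by LF walks. Two small arrays make every walk terminate
correctly in a multi-sequence text:

- an explicit LF permutation for sentinel rows (one entry per
  sequence): with several equal sentinels, rank-derived LF is not
  consistent with the suffix array at the wraparound row, so the
  correct targets are recorded at build time, keeping
  `LF(p) = row(SA[p] − 1 mod n)` everywhere and the LF orbit a single
  n-cycle;
- for each sentinel-block row, the ID of the sequence *following* that
  terminator in the text (wrapping at the end). When a walk reaches a
  row whose BWT character is the sentinel it has hit the first
  character of the sequence being resolved; one LF step lands in the
  sentinel block and this array supplies the answer without crossing
  into the neighboring sequence.

Resolution is verified against a retained suffix array at every BWT
position in the test suite, for all four representations.

## Classification parameters

| parameter | default | meaning |
| --- | --- | --- |
| `report_threshold` | 1 | max assignments per read; ties merge to LCAs |
| minimum match length | derived | smallest `l` with `2n/4^l ≤ 0.01`; 23 at n = 140 Gbp, 13–14 at the megabase scale of the synthetic databases |
| score offset | 15 | score is `(l_M − 15)²` per valid match |
| resolve cap | 40·threshold | evenly spaced rows resolved per match interval (endpoints included, round-to-nearest spacing, de-duplicated) |
| sample rate | 16 | BWT rows between stored sequence IDs |

Matches are always emitted by the scan and filtered afterwards, so the
skip-and-restart structure of the search never depends on the filter.
`N` in a read matches nothing: it terminates the current match and is
skipped like any mismatch. Strand ties keep both strands' matches.
Paired reads are scanned as mate1-forward + mate2-reverse against
mate1-reverse + mate2-forward (FR orientation) before strand selection,
and per-sequence scores sum over both mates. When several sequences tie
at the top score, sequences sharing a taxonomy ID collapse first; if
the distinct taxonomy IDs still exceed the threshold they merge
pairwise, deepest LCA first (ties to smaller IDs) — the merge schedule
is a package choice, as is reporting the sequence label only when a
single sequence uniquely wins. Stale taxonomy IDs absent from the tree
fall back to the root with a warning. The classify path contains no
randomness; identical inputs give identical outputs, independent of
the thread count (reads are processed in fixed-order batches).

Scores shorter than the 15-base offset can only arise for databases
under ~100 kb, where the derived minimum length drops below 15; the
printed quadratic is applied as-is (it is positive on both sides of the
offset).

## Synthetic data

The generator emulates a strain-level database: each species is an
independent uniform-random genome; strains are copies with independent
per-site substitutions (a drawn mutation always changes the base).
Defaults — 4 species × 5 strains of 10 kb, 1% strain mutations, 10,000
single-end 100-bp reads at 0.5% substitution error — give a ~200 kb
text with BWT average run length well above the unrelated-genome
baseline, a scale at which the full pipeline (build + 10k reads) runs
in under a minute while still exercising shared and unique regions.
The 10 kb genome length is the package's desk-scale choice; mutation
and error rates follow the strain-divergence and error conditions the
recovery checks specify. Reads carry substitution errors only: the
classifier is exact-match based, and indels would only shorten matches
without exercising different code paths. Quality strings are constant.

What passing recovery tests show — and what they do not: with species
drawn independently, cross-species false assignment is essentially
impossible at the derived match-length floor, so the zero-escape check
validates the scoring/LCA path rather than discrimination between
related species. Real databases have inter-species homology,
low-complexity sequence, and indel errors; accuracy numbers measured on
the synthetic fixture do not transfer to them.

The evaluation harness defines sensitivity as TP/T and precision as
TP/P, where TP counts reads whose reported taxon lies at the evaluated
node or in its subtree, T is all reads, and P is reads classified at or
below the evaluated rank.

## Known limitations

- Suffix construction holds the text and suffix array in memory;
  gigabase databases would need external or blockwise sorting.
- No genome-offset sampling: the index cannot report match coordinates,
  only sequence identity (a deliberate space saving).
- No protein alphabet, no Huffman-shaped wavelet trees, no select
  structures beyond binary search, no abundance re-estimation; the
  Kraken-style report is the hand-off point for downstream profilers.
- Rank queries are scalar Python; throughput (~300 reads/s on the
  synthetic fixture) is adequate for the intended desk scale, not for
  production-size runs.
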