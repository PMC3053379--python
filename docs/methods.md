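# Methods

This note records the models, conventions and numerical choices behind
`mitocompare`, in the order the pipeline applies them.

## Circular coordinates

All sequences are circular unless declared linear. Coordinates are 0-based,
half-open, on the forward strand; an interval with `start > end` wraps the
origin and denotes `[start, L) ∪ [0, end)`. Library functions report
coordinates in the rotation they were given; the pipeline (`run_compare`)
rotates both genomes to their lexicographically minimal rotation (Booth's
algorithm) at load time, so its reports are independent of how the input
records happened to be linearized. Equality of circular sequences is
defined up to rotation only — the two strands of a deposited genome are
distinguishable, so reflection is not a symmetry here.

## Synteny blocks

Detection is seed–chain–align:

1. **Anchors.** Maximal exact matches of length ≥ k (default k = 15) on
   both strands, found by k-mer indexing of the doubled linearizations and
   merged along diagonals. Doubling plus de-duplication modulo L makes
   origin-spanning blocks ordinary.
2. **Chaining.** Anchors are chained greedily in reference order; a chain
   accepts an anchor when the reference gap and the diagonal drift are both
   within `max_gap` (default 100 bp). `max_gap` therefore sets the largest
   internal indel a block may contain and the smallest junction insertion
   that splits two blocks.
3. **Alignment and filtering.** Each chain's two spans are globally aligned
   with edlib; identity is matching columns over all columns, gaps
   included — the conservative reading of "percent similarity". Blocks
   need ≥ `min_len` columns (default 2000) and identity ≥ `min_identity`
   (default 0.99, compared as ≥).
4. **Disjointness.** Candidates are retained longest-first; a candidate
   overlapping a retained block by more than half its length is dropped,
   smaller overlaps are trimmed by walking the alignment (so both
   coordinate systems stay consistent). Longest-first is deliberate: a
   shared multi-kilobase repeat aligns its copies across genomes at ~100%
   identity, and an identity-first rule would let those spurious
   repeat-to-repeat blocks fragment the long syntenic regions that contain
   them.

Blocks are numbered 1..n along the reference. The mitotype-specific
fraction of a genome is the fraction covered by no block; block boundaries
can absorb the occasional chance-matching base at a junction, so specific
fractions carry a few bp of fuzz per junction.

## Rearrangement distance

The query's blocks, ordered by query start with signs from block strands,
form a signed circular permutation (normalized by rotating block 1 first
and reflecting if its sign is negative). The minimum recombination-event
count is the DCJ distance *d = n − c*, where *c* counts cycles in the
breakpoint graph on block extremities. DCJ treats an inversion as one event
and a cut-and-paste transposition as two; this is stated in every report
(`model: dcj`), because repeat-mediated recombination generates both kinds
of event and the literature's informal "recombination event" counts do not
fix an algebra. An inversion-only distance is available for small *n* via
bidirectional BFS (`inversion_only_distance`). `brute_force_distance` is an
exhaustive BFS over all perfect matchings of block extremities (all
multichromosomal circular genomes), used as the test oracle; the identity
*d = n − c* is verified against it exhaustively for n ≤ 5 and on random
permutations for n = 6–7.

A consequence worth recording: an 11-block circular permutation at DCJ
distance 5 must retain at least one conserved adjacency (6 cycles cannot
all be non-trivial across 11 adjacencies), so a genome pair showing eleven
*detected* regions at distance five necessarily has junction-level
insertions separating regions that rearrangement alone would have left
fused. The full-scale profile reflects that: specific segments sit at every
junction.

## Repeats

Dispersed repeats follow the classic definition: equal-length copy pairs,
30–500 bp, ≥ 90% identical under an ungapped (Hamming) comparison — the
only reading under which "identical length" is meaningful. Equal-length
ungapped pairs live on diagonals (direct) or anti-diagonals (inverted) of
the circular self-comparison, so detection scans diagonals:

- **Window rule.** A reported pair is a maximal window whose ends are
  matches, whose identity is ≥ the threshold, and which cannot absorb the
  adjacent mismatch gap *g* plus following exact run *r* while keeping
  identity ≥ threshold and *r ≥ 3g*. The local-support condition *r ≥ 3g*
  stops windows from creeping into random flanking sequence (an unbounded
  absorb rule would drag identity down to the threshold on pure noise);
  maximal windows still absorb chance-matching flank bases, so a planted
  2,427 bp exact pair may be reported at 2,427–2,430 bp.
- **Seeding is complete.** Any qualifying window of length ℓ with
  m ≤ (1−θ)ℓ mismatches contains an exact run of ≥ ⌈(ℓ−m)/(m+1)⌉ bases
  (pigeonhole); minimized over admissible ℓ this gives the seed bound
  (7 bp at the 30 bp/90% defaults — `guaranteed_seed`). The k-mer seed is
  shortened to this bound whenever the configured `seed_len` exceeds it.
  At genome scale, a vectorized local-density prefilter (some min_len
  window around the seed must already hold the threshold match count —
  also implied by any qualifying window) discards the flood of chance
  short seeds without losing completeness.
- Copies that overlap each other (tandem-like) are not reported; windows
  whose maximal extension exceeds `max_len` belong to the large-repeat
  scan. Pairs sharing a copy locus (reciprocal overlap ≥ half the shorter
  copy) are grouped into families by single linkage.

Large repeats use the same machinery at ≥ 1 kb / ≥ 99%. Repeat coverage is
the union of all copy loci over L. The brute-force oracle in
`tests/repeat_oracle.py` re-implements the same stated rule by
exhaustively materializing every (anti-)diagonal; detector and oracle must
agree exactly on desk-scale genomes.

Recombination across a *direct* repeat pair splits the master circle into
two circles of lengths `(start_b − start_a) mod L` and the complement, each
retaining one copy; the lengths sum to L by construction. Inverted pairs
yield an inversion isomer instead and are rejected with that explanation.

## Junctions

For a block's query-side edge, the junction to the next block in query
order is classified `collinear` (the neighbour continues on the reference
in the same orientation within the window) or `rearrangement`. Collinear
junctions quantify the reference arc skipped between the blocks (lost
sequence) and the query gap (inserted sequence); an insertion with no
≥ 90%-identity hit anywhere else in either genome is labelled *anonymous*.
With a `probe` interval (e.g. a disrupted reading frame spanning the
junction) both probe ends are anchored on the reference and extended
inwards under the same gap/run absorb rule; the anchored extensions give
the shared prefix/suffix lengths and the reference arc between them the
internal loss. Anchoring both ends separately matters: a single
edit-distance alignment prefers mismatching a short flank over paying for
a long deletion and would hide exactly the signal being measured.

## SNP census

SNPs are called only inside retained blocks — specific sequence has no
homologous counterpart, which makes the denominator explicit. Mismatch
columns within `gap_exclusion_bp` (default 5) of an indel are excluded as
potential alignment artifacts. Transitions are A↔G and C↔T. The reported
rate is 10,000 · n / denominator; the pipeline defaults to the genome
length as denominator and also records the aligned column count, since the
two conventions differ by a few percent whenever specific sequence exists.
For minus-strand blocks the query base is reported in alignment
orientation (complemented), so the ref→qry change reads off the homologous
strands; VCF output is 1-based on the reference. ORF similarity is global
alignment identity (columns including gaps) at the nucleotide level and,
after standard-code translation (plant mitochondria use the standard
code; internal stops truncate with a warning), at the peptide level.

## Assay layer

The primer binding model is deliberately explicit rather than
thermodynamic: a site requires an exact match over the 3′-most
`seed_3prime` bases (default 10) and at most `max_mismatch_5prime`
(default 2) mismatches elsewhere. Every primer is scanned on both strands
of the doubled template, so products are found under any rotation and on
either strand, including origin-spanning products; any two convergent
sites within `max_product` (default 5 kb) form an amplicon, and pooled
identical oligos are counted once. Efficiency comes from the dilution-series
slope, E = 10^(−1/slope) − 1 (perfect doubling: slope −3.3219, E = 1).
Copy ratios use per-target efficiencies, ratio = (1+E_b)^Ct_b /
(1+E_a)^Ct_a with Ct the arithmetic mean of replicates; reciprocity
ratio(a,b)·ratio(b,a) = 1 holds exactly. The Ct simulator inverts the same
model (Ct = C0 − log copies / log(1+E), C0 = 40 at one copy) plus Gaussian
cycle noise; with equal efficiencies the instrument constant cancels from
the ratio, with unequal efficiencies it does not — a limitation shared
with any ΔCt-style method.

## Synthetic data: what it emulates, and what it does not

The generator derives a query mitotype from a block-structured ancestor:
structural events on whole blocks (inversion, transposition, duplication,
deletion), novel-segment insertions at junctions (mitotype-specific
sequence; inserted material is uniform-random, as befits sequence of
unknown origin), small within-block indels, and SNPs. Everything is logged
and the log replays byte-exactly. Residue content is i.i.d. with a
configurable G+C fraction (default 0.45; the full-scale profile uses
0.4522, typical of crucifer mitochondria).

Deliberate idealizations, relevant when reading test results: real
mitogenomes have compositional heterogeneity, tandem microsatellites,
chloroplast-derived insertions and gene-density structure, none of which
are modeled; planted repeat copies degrade by evenly spaced substitutions
(the mismatch count is capped so the planted identity is ≥ the request and
every internal run is long enough that a threshold-matched detector can
absorb the whole copy — randomly clustered mismatches can legitimately
fragment a copy into sub-threshold windows, which is a property of the
definition, not a detector defect); exact-count SNP planting keeps 25 bp
from block edges (an anchor length, so flanking seeds survive) and 8 bp
between SNPs (outside each other's gap-exclusion window and clear of
alignment ties). Passing recovery tests therefore demonstrates
correctness of the detectors under the stated definitions, not robustness
to every feature of real data.

Test scale: unit tests run at 4–80 kb; the rearrangement-recovery check
uses 50 kb genomes with 10 blocks over 50 replicates per event count; the
repeat oracle runs 20 genomes of 10 kb; the SNP-census check and the
acceptance script run at the full 223,412 bp.

## The full-scale profile

`mitocompare.profiles.polnap_profile` encodes a published two-mitotype
configuration as *inputs*: reference length 223,412 bp at 45.22% G+C,
eleven blocks (three inverted) separated by specific segments totalling
4.53% of the reference and 3.63% of the query, five DCJ events (three
single-block inversions plus one transposition), a 2,427 bp direct pair at
86,232 bp start separation (so the excised circles are 86.2 kb and
137.1–137.2 kb), dispersed repeats covering 4.75%, 197 SNPs (102:95), and
+509 bp of within-block query insertions — the unique value making the
specific fractions and the 1,559 bp length difference simultaneously
consistent. The seed randomizes residue content and placements only; the
structural constants are fixed design inputs, and the pipeline recomputes
all of them as outputs.

## Known limitations

- DCJ counts transpositions as two events; distances are model-dependent
  and labelled as such.
- The repeat scanner's per-k-mer occurrence lists assume random-ish
  composition; highly repetitive (e.g. microsatellite-dense) genomes would
  inflate the seed-pair set.
- Junction probe analysis assumes the probe's end anchors occur once in
  the reference; paralogous anchors would need disambiguation.
- Multi-genome (> 2) synteny, annotation, tandem repeats, and sublimon
  population dynamics are out of scope.
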