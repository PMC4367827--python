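# Methods

`bactrokit` re-implements, as one tested pipeline, the raw-read analyses a
draft-genome project performs around its assembly: k-mer–extension repeat
discovery, satellite tandem-array statistics, two genome-size estimators,
fixed-difference calling between sibling species with region partitioning
and codon-effect classification, zero-coverage deletion detection, a
repeat-association permutation test, and transposon insert-span comparison.
Everything is exercisable on synthetic data with exact truth bookkeeping,
so each caller's recall and precision can be measured.

## The synthetic data generator

The generator (`bactrokit.simulate`) emulates the statistical structure
every downstream stage assumes, at desk scale:

- a genome of `length` (default 2 Mbp; the real target is hundreds of Mbp)
  of i.i.d. uniform ACGT background;
- alphoid-style satellites: monomers with lengths drawn from
  `satellite_monomer_lengths` (defaults 166 and 178 bp, inside the
  154–182 bp range typical of this satellite class), each repeated
  head-to-tail `satellite_copies` times (500 and 200) in one array;
- a dispersed DNA-transposon: one canonical random sequence of
  `transposon_length` (1.5 kb, the canonical mariner-type length) planted
  `transposon_insertions` times (40), a `transposon_fragmentation` fraction
  (0.5) of copies planted as internal fragments of at least 200 bp;
- `n_genes` (100) gene-like segments with 5'UTR + CDS exon + intron + CDS
  exon + 3'UTR structure, lengths in `gene_length_range` (900–1500 bp);
  CDSs start with ATG, contain no internal stop codons, and are split
  across two exons at a codon-interior point so that the GFF3 phase column
  is non-trivial;
- reads: uniform start positions, both strands with probability 0.5,
  `read_len` 100 bp, i.i.d. substitution errors at `error_rate` (0.005),
  `paired` fragments with `insert_mean` 300 / `insert_sd` 30, constant 'I'
  placeholder qualities.  `depth` (35x) matches the coverage used for the
  size-estimation checks; the sibling read set is simulated at
  `depth_sibling` (70x), mirroring the deep resequencing that zero-coverage
  deletion screening requires — the bases bordering a deletion breakpoint
  are covered only by reads anchored on that side, roughly halving the
  usable depth there, and the 20x flank floor must still clear.

A sibling species is derived by per-region substitution (`rate_exon`
0.003, `rate_intron` 0.006, `rate_utr5` 0.0036, `rate_utr3` 0.0026,
`rate_noncoding` 0.007 — the coding-most-constrained ordering observed
between true sibling tephritids), `n_deletions` (30) non-overlapping
deletions with lengths in `deletion_length_range` (15–80 bp) auto-placed
in feature-free sequence, and per-element length jitter drawn as a normal
with `transposon_jitter_sd` (50 bp) applied inside each planted transposon
copy.  All coordinates are 0-based half-open; every edit is recorded in a
truth set sufficient to score recall and precision.

What the generator deliberately does not model: indel sequencing errors,
quality-score structure, GC bias, heterozygosity (the emulated study used
inbred material and called near-homozygous variants), jumping libraries,
and higher-order satellite structure.  Passing tests therefore demonstrate
algorithmic correctness under clean mapping statistics, not robustness to
every artefact of real libraries.

## Read mapping and the alignment contract

The internal mapper exists so the pipeline is testable without an external
aligner; all downstream stages consume only the `Alignment`/`Pileup`
contract, and SAM import can substitute a different mapper.  Exact seeds
of `seed_len` (19 bp, the smallest segment the emulated protocol mapped)
index the reference; candidate diagonals come from seed hits on both
strands.  Scoring is match +1, mismatch −1, gap open −3, gap extend −1;
ties break to the leftmost placement.  Mapping quality is binary by
design: a unique best placement gets q=60, ties get q=0, so the
thresholds `q_general` (20, general retention), `q_transcript_initial`
(29, i.e. discarding q<30 on the first transcript mapping) and `q_unique`
(55, unique-mapping passes) act as the emulated protocol's filters.

Every candidate is scored in its final *end-trimmed* form: the maximal
+1/−1-scoring stretch is kept and the ends become soft clips, so a cleanly
clipped placement competes fairly with a gapped one (the gapped aligner is
only consulted where it could win, which is what makes deletion-spanning
reads produce a D operation for short deletions and clean clips for long
ones).  Two numerical rules matter at breakpoints:

- terminal blocks shorter than 25 aligned bases beyond an indel are
  pruned — chance micro-alignments of a read tail inside a deleted region
  would otherwise fragment genuine zero-coverage runs;
- a trimmed end must close with ≥6 exact matches, or a ≥2-base terminal
  run separated by exactly one mismatch from a run with combined length
  ≥12.  The second clause keeps a real substitution sitting next to a
  breakpoint from stripping genuine coverage; the first keeps chance tail
  matches (p=1/4 per base) out.

Coverage tracks count M operations only (a deletion op leaves its span
uncovered, as per-base coverage utilities do), optionally restricted to
reads whose mate also mapped.

## k-mer counting and genome size

Counting is exact over 2-bit-packed codes (k ≤ 31).  `k_discovery` (18)
drives discovery and abundance; `k_arrange` (12) the spacing statistics,
trading specificity for counting speed exactly as the emulated analysis
did.  The histogram estimator divides total k-mer occurrences by the
main-peak multiplicity; numerically, the error trough is the first rise of
the raw spectrum, occurrences at or below it are excluded from the total,
and the peak is refined by a centroid over a ±0.5-peak band re-centred
three times (the integer mode understates the mean of the Poisson-like
single-copy peak by several percent).

The coverage estimator maps reads to transcript-like genomic segments
(with `segment_flank` 100 bp excluded from summaries), drops the
<`coverage_low` (10) and >`coverage_high` (60) bands, keeps the median 50%
of segments ranked by coverage (ties by id), drops segments with ≥5
consecutive Ns or an annotation-quality score above `aed_max` (0.2), and
summarises each segment by its median depth; genome size = total
sequenced bases / histogram mode of those medians (bin width 1, +0.5
centre).  The band cut is applied before the rank-median, matching the
order in which the emulated analysis reports its exclusions.

## Repeat discovery

Greedy extension walks the as-read 18-mer table: seeds in descending count
order (`top_n_seeds` 50000), extending one base at a time through the
highest-count unconsumed k-mer with a 17-mer overlap, both directions, no
k-mer used twice.  A walk direction stops when the chosen k-mer was
already consumed (a tandem monomer thereby closes on its own seed and is
reported in lexicographically minimal rotation), when no candidate with
count ≥ `min_count` (2, excluding error k-mers) remains, when the
candidate count collapses below `stop_ratio` (0.2) of the previous step
(a repeat/unique boundary — without this, walks continue through
single-copy sequence indefinitely, which the short fragments reported by
the emulated analysis show cannot have happened), or at `max_walk_len`
(10 kb).  Walks shorter than k + `min_extension` (50) are discarded —
"extended more than 50 bp" is read as final length ≥ 68 bp.

`align_and_extend` finds assembly matches at ≥ `min_identity` (0.80),
extracts them with up to `align_flank` (200 bp) of flanking sequence, and
extends the consensus column-by-column while ≥ `consensus_threshold`
(0.60) of ≥ `min_support` (3) covering segments agree, iterating until no
growth.  Finalisation installs per-position majority bases from a read
pileup (short entries are tandem-tiled so junction reads align; tied
placements congruent modulo the monomer length count as one placement) and
culls entries above `max_library_identity` (0.80) to a longer entry,
comparing circular entries against the doubled sequence so rotations and
reverse complements collapse.  Species-specific libraries substitute every
site where the sibling majority allele exceeds `variant_min_freq` (0.5,
strict) and apply 1–2 bp indels the same way.

## Satellite statistics

Arrangement is read, not assembled: the monomer is tiled with
non-overlapping 12-mers; for every read containing the anchor (position-0
tiling 12-mer, up to one substitution) the signed offsets and orientations
of the other tiling 12-mers are accumulated in the anchor-forward frame.
The analytic expectation for a co-occurrence at offset d on R bp reads is
(R−k−|d|+1)/(R−k+1).  Head-to-tail classification requires ≥90% of
co-occurrences on the expected offsets in consistent orientation *and*
junction-wrapped (negative) offsets at ≥50% of their analytic share —
without the second condition, dispersed single copies (whose intra-monomer
offsets are also "expected") would classify as tandem.  Orientation flips
above 20% classify head-to-head; otherwise dispersed.

Abundance divides observed tiling 18-mer counts by the k-mer-level depth
(base depth × (R−k+1)/R, made explicit).  Variable counts add
single-substitution neighbours (plus single-indel neighbours when k−1/k+1
tables are supplied), screening out neighbours that occur verbatim in the
doubled canonical monomer, which would re-count canonical copies.

## Divergence and structural comparison

Fixed differences require depth ≥ `min_depth` (10) and alternate frequency
≥ `homozygous_freq` (0.9, the near-homozygous regime of the emulated
caller); rates are per *callable* site (depth ≥ 10) per region class, with
precedence exon > UTR > intron for overlapping annotations.  Coding
effects are evaluated jointly over all fixed differences in a codon using
the standard genetic code: a codon is a novel stop only if the jointly
mutated codon is a stop; a substitution that would create a stop in
isolation but is negated by a second substitution in the same codon is
reported as compensated.  1–2 bp indels in exons count as non-synonymous.
Both the raw dN/dS (non-synonymous rate over synonymous rate per callable
exon site) and a per-opportunity-normalised ratio (using the mean
synonymous-site fraction of the annotated codons) are reported, since the
two readings differ by the ~3:1 site-opportunity factor.

Deletions are maximal zero-coverage runs longer than `min_len` (10 bp) in
the paired, quality-filtered sibling mapping whose two `flank_len` (10 bp)
borders are each entirely above `flank_min_cov` (20x), the strictest
reading of the flank requirement.  Before run detection the track is
denoised: islands of ≤ `noise_len` (8) bases at depth ≤ `noise_cov` (2)
adjacent to zero coverage are treated as unsupported (a single sequencing
error at a breakpoint-adjacent base recreates the reference allele in one
read), and "shoulders" at ≤35% of the local flank depth next to a zero
run are zeroed as well — the minority of junction reads that soft-clip
rather than carry a deletion operation extends a few micro-homology bases
past the breakpoint.  Well-supported coverage (a genuine half-depth
micro-homology shift, for instance) is never touched.  Breakpoint micro-homology shifts
run boundaries by a few bases in a way no read evidence can resolve, so
recovery is scored with ±6 bp of slack.

The association test asks whether deletion flanks (`flank` 1000 bp)
contain repeat-library hits (a blast-like surrogate: ≥ `min_hit_len`
80 bp at `identity` 0.80, implemented as a shared-12-mer density mask)
more often than `n_permutations` (1000) random placements of the same
intervals, each control pair separated by the matching deletion's length;
p is one-sided with add-one correction.

Element spans: fragments of the canonical transposon within `merge_dist`
(1.5 kb, the canonical element length `canonical_len`) merge into one
element, split at the largest internal gap when the extent reaches twice
the canonical length; 1000 bp flanks are taken outside the merged extent.
Each flank pair is located in the sibling (unique, same contig, same
orientation, near-full-length at ≤2% divergence — a repeat-dominated
flank can otherwise land on the wrong copy with a respectable score) and
the absolute span change is compared against matched random controls by a
two-tailed Welch t-test (variances are not assumed equal).

## Seeds and problem sizes

A single global `seed` fans out to per-stage seeds by fixed offsets.  The
default dataset — 2 Mbp, 35x reads, 70x sibling reads — is the size at
which every stage's statistical check (5% size recovery, 3-s.d. rate
recovery, ≥0.95 deletion precision/recall, p-value behaviour of the
permutation and span tests) is comfortably powered while a full pipeline
run stays in the minutes range on one core.

## Known limitations

- The mapper has no paired-end rescue and binary mapping quality; subtle
  multi-mapping biases of real aligners are not reproduced.
- Repeat classification (LINE/LTR/DNA family labels) is accepted from
  configuration, never inferred by homology.
- The rRNA profiling utilities operate on a supplied consensus and region
  annotation; they do not assemble the unit de novo.
- Abundance estimates assume uniform coverage; GC-dependent coverage in
  real libraries would bias them.
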