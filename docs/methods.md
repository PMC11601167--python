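# Methods

## Detection model

A non-reference TE insertion in a long-read alignment manifests as (a)
CIGAR insertion operations in reads spanning the event and (b) soft
clips in reads whose alignment terminates inside it.  `retrofind`
treats both uniformly as *insertion evidence*: a breakpoint position
(0-based; for an `I` op the first reference base right of the op, for a
clip the read's reference start/end), the candidate sequence (inserted
or clipped bases), and the read's HP/PS phasing tags if present.

Only primary, non-duplicate, non-QC-fail alignments at or above the
MAPQ threshold contribute.  Supplementary alignments are deliberately
ignored: the sequence needed for classification lives in the primary
record's soft-clipped bases, and the two flanks of a long insertion
each produce a primary clip at the same breakpoint, so split alignments
still generate clustered evidence.  Hard clips carry no sequence and
are only counted.  Candidate sequences are kept in read orientation;
strand is resolved later by the TE aligner.

## Clustering

Breakpoints of one insertion are scattered over a few bp (tens of bp at
high error rates near long events), while true loci are far apart.
DBSCAN on the 1-D position axis separates the two regimes without
assuming the number of loci.  The implementation is the textbook
algorithm specialised to sorted positions: neighbourhood queries are
binary-searched windows, points are processed left to right, and labels
are provably identical to generic DBSCAN (verified against a brute-force
O(n²) oracle and scikit-learn's implementation in the test suite).
Insertion-op and clip evidence are clustered jointly in one pass.

## Classification and filtering

Every cluster member's candidate sequence is realigned to the TE
library.  All clusters are batched into a single aligner invocation;
correctness is invariant to batching (tested).  Two engines satisfy the
same contract — best target per candidate with target name, query
aligned length and strand; ties broken by longer aligned length, then
lexicographic name:

- **minimap2** (default when on PATH): PAF output, `map-pb` preset,
  `--secondary=no`; the hit score is the residue-match count.
- **edlib** (built-in fallback): infix alignment of the candidate (and
  its reverse complement) into each target.  edlib has no true local
  mode, so the whole candidate must fit into a target; a hit is
  reported at ≥ 0.7 full-query identity (random sequence scores ≈ 0.5,
  a TE copy at ~12% read error > 0.8) and the aligned length is the
  query length.  This is sufficient for candidate sequences that are
  whole or truncated TE copies — the situation in hermetic direct-BAM
  runs — whereas minimap2 handles clips carrying flanking sequence
  exactly.

A match is *valid* when its aligned length is at least `match_fraction`
(default 0.10) of the candidate sequence length — the fraction is of
the candidate, not of the TE consensus, so heavily clipped reads are
judged against what they actually carry.  A cluster passes when at
least `min_supporting_reads` (default 3) valid matches agree on one
family; the per-family (rather than any-TE) requirement favours
precision on mixed clusters.  Family ties break by cumulative aligned
length, then name.  An optional two-column TSV maps library entry names
to families so subfamily libraries vote jointly.

## Refinement and genotyping

The call position is the lower median of supporting breakpoints (robust
to stray clip positions; lower-median for determinism on even counts),
and the reported insert length is the lower median of supporting
sequence lengths — an underestimate for insertions longer than the
typical read overhang, since clipped reads carry only part of the
event.

Genotypes use read phasing when available: with ≥ 80% of
haplotype-tagged supporting reads on one haplotype the call is a phased
heterozygote on that haplotype; support on both haplotypes yields a
homozygous call.  Without tags, the call is an unphased heterozygote,
upgraded to homozygous when supporting reads account for ≥ 80% of the
local depth (primary MAPQ-passing reads overlapping the consensus
position); zero depth yields `./.` while the call is retained.  The two
0.8 thresholds are package conventions, both configurable; genotyping
never changes a call's position, family or support count.

## VCF contract

VCF 4.2 with symbolic ALT alleles `<INS:ME:FAMILY>` (no insertion
consensus is assembled, so no sequence ALT), INFO
`SVTYPE/SVLEN/END/TEFAMILY/SUPPORT`, per-sample `GT:DP:HS` where HS is
(haplotype-1, haplotype-2, unphased) supporting-read counts, and `|`
separators only for haplotype-resolved genotypes.  Positions are
0-based half-open internally and converted to 1-based only at write
time.  Output is asserted to round-trip through a standard VCF parser.

## Synthetic benchmark

The generator emulates a standard caller-evaluation design: plant
full-length TE copies into a TE-free background and sequence the result
with noisy long reads.

- **Genome**: seeded uniform-random A/C/G/T, default 5 Mb, one contig.
  No TE homology exists in the background, so false positives measure
  caller artefacts, not repeat confusion.
- **TE library**: one synthetic consensus per family at realistic
  full lengths — Alu 300, SVA 1800, L1 6000, HERV 9500 bp.  These are
  seeded random sequences standing in for real consensus sequences; the
  benchmark therefore does not probe subfamily divergence or the
  repeat-rich context of real genomes.
- **Insertions**: default 60 Alu, 60 L1, 30 HERV, 30 SVA, homozygous,
  uniform-random positions with ≥ 1 kb spacing and ≥ 1 kb from contig
  ends.  A `het_fraction` option places events on one random haplotype
  to exercise phased genotyping.
- **Reads**: drawn uniformly from both haplotypes to 20× combined
  coverage; lengths truncated-normal (mean 12 kb, sd 3 kb, min 1 kb),
  consistent with later-chemistry PacBio RS II runs; per-base errors at
  6% mismatch, 3% insertion, 3% deletion (~12% total).  Half the reads
  are reverse-strand.  Reads are tagged HP:1/2 by source haplotype,
  emulating perfectly haplotagged input; FASTQ output carries the tags
  as SAM-style comments that `minimap2 -y` propagates.
- **Direct-BAM mode** writes each read's *true* alignment to the
  un-inserted reference with the exact CIGAR (planted insertions as `I`
  ops, reads ending inside an insertion soft-clipped, error
  insertions/deletions as `I`/`D`), bypassing the aligner for hermetic,
  deterministic tests.  Reads falling entirely inside an insertion are
  dropped from the BAM (counted in the manifest).  In the error-free
  direct-BAM limit the caller must achieve sensitivity and precision
  1.0 for every family — the closed-form check in the test suite.
- **Evaluation**: one-to-one greedy distance matching within a 50 bp
  window, family-exact.  The window covers observed breakpoint jitter
  at 12% error; it is exposed as `--window`.

What passing these benchmarks does *not* show: performance on real
genomes with diverged, truncated, nested or reference-adjacent
elements, 5′-truncated L1s (a truncation option exists but the headline
benchmark plants full-length copies), target-site duplications, poly-A
tails, or ONT-specific error structure.

## Problem sizes and numerical choices

The shipped benchmark uses a 5 Mb genome at 20× (≈ 100 Mb of read
bases, ≈ 180 loci), chosen so the complete simulate-align-call-evaluate
cycle runs in about a minute on one CPU while every family retains
30–60 events for binomially meaningful sensitivity estimates.  All
randomness flows from a single integer seed through independent
`numpy` `default_rng` streams (genome, planting, reads), so every
artefact is byte-reproducible per seed.  Defaults of note:

| parameter | default | rationale |
| --- | --- | --- |
| `min_insertion_len` | 100 bp | keeps truncated Alu detectable, suppresses small-indel noise |
| `min_clip_len` | 150 bp | terminal clips shorter than this are dominated by alignment-end noise |
| `min_mapq` | 10 | drops ambiguous placements without losing most long reads |
| `cluster_eps` | 100 bp | breakpoint jitter is tens of bp; 100 keeps neighbouring het loci apart |
| `cluster_min_points` | = `--sr` | one knob controls cluster density and call support |
| `match_fraction` | 0.10 | a clip may carry only the edge of a long element |
| `match_window_bp` | 50 | evaluation window, covers jitter at 12% error |

Degenerate inputs: empty BAM and empty call lists produce valid empty
outputs; an unindexed BAM, unknown region contig, empty TE FASTA,
unsorted calls and unknown VCF contigs are fatal with explicit
messages.

## Known limitations

Reference TE polymorphisms (elements present in the reference but
absent from the sample) are deletions, not insertions, and are out of
scope.  Hard-clipped supplementary pairs are not used as evidence.  The
insert-length estimate is a lower bound for elements longer than the
read overhang.  Genotype accuracy degrades without phasing tags at
uneven local depth.  Multi-sample joint calling and gVCF output are not
provided.
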