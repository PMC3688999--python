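# Methods

This note documents the models, algorithms, parameter choices and
limitations behind each module, and what the synthetic-data generator
does and does not emulate.

## Coordinates and circular arithmetic

All coordinates are 0-based half-open; GenBank's 1-based inclusive
convention exists only at the I/O boundary. On a circle of length *n* an
interval may have `end > n` to denote an origin wrap; every length, gap,
overlap and fetch operation goes through one interval utility
(`plastocomp.intervals`) so the wrap convention has a single source of
truth. Origin-wrapping features are stored as parts with a wrap flag and
round-trip through GenBank `join(...)` locations.

## Quadripartite structure

`find_ir` detects the inverted repeat as the longest pair of **disjoint,
maximal, exactly reverse-complementary** intervals, by hashing 21-bp words
of the reverse complement and extending matches along diagonals over the
doubled sequence (so repeats may wrap the origin). Exact identity is the
default because real IR copies are homogenized by recombination and
near-identical; a mismatch-tolerant mode is out of scope. Maximality makes
the junction coordinates well defined: extending either interval by one
base breaks the identity. Minimum IR length defaults to 1,000 bp, which is
far above the longest inverted match expected by chance in a 160-kb random
sequence and below every real plastome IR.

The two single-copy gaps between the IR copies become LSC (the larger;
ties go to the one first encountered from the origin) and SSC, and IRb is
the copy immediately downstream of the LSC. Junctions are named JLB, JSB,
JSA, JLA; a junction coordinate is the first base of the downstream
region, and "within gene" uses the feature's full span including introns,
under the half-open convention (a junction at a feature's first base is
inside it).

## SSR scanning

An SSR is a maximal perfect tandem repeat of a primitive motif (not a
power of a shorter unit) of 1–6 bp reaching a per-unit-length minimum
repeat count — defaults 10, 5, 4, 3, 3, 3 for mono- through
hexanucleotides. Reporting at the smallest period plus the primitivity
rule guarantees each locus appears exactly once (an A₁₂ run is one
mononucleotide SSR, never an (AA)₆ dinucleotide); a periodic span whose
length is not a motif multiple is anchored at its leftmost full repeat.
Scanning runs on the doubled sequence with a left-maximality check at the
origin so circular wrap loci are counted once. A genome that is globally
periodic (the whole circle one repeat) is not supported; this cannot occur
in practice. The scanner is validated against an exhaustive
(start, period, extension) oracle in the test suite.

Cross-genome conservation: an SSR is conserved when a partner in the other
genome has the identical as-occurs motif, the same region class (coding /
intron / intergenic; majority label of the interval, ties to the first
base), and both 100-bp flank windows align globally with ≥ 60% identity
(match +1 / mismatch −1 / gap open −5 / gap extend −1). Pairing is greedy
one-to-one by descending mean flank identity. Flank length, identity
threshold and alignment scores are configuration keys; the defaults are
our choices since no standard exists, and the synthetic tests plant SSRs
whose classification is unambiguous under any reasonable setting. SSRs in
both IR copies are counted once per copy so whole-genome totals match
map-style reporting; flanks containing runs of N are reported as
unassessable rather than forced into either class.

## Intergenic spacer divergence and marker selection

Spacers are maximal intergenic runs of the region map (coding > intron >
intergenic priority; pseudogenes do not count as coding), named
`gene1-gene2` after the flanking genes in genome order, with the run
wrapping the origin merged into one spacer and IR-duplicated spacers
collapsed to the IRb copy. Spacers flanking pseudogenized or absent genes
can be excluded per comparison. Homologs are matched by the unordered
flanking-gene name pair.

Distances are computed on a global pairwise alignment (same affine scheme
as above) using only gap-free columns (complete deletion within the pair):

* p — proportion of differing sites;
* JC — `d = -3/4 · ln(1 - 4p/3)`;
* F84 — Felsenstein's closed form
  `d = -2A·ln(1 - P/(2A) - (A-B)Q/(2AC)) + 2(A-B-C)·ln(1 - Q/(2C))`
  with `A = π_Cπ_T/π_Y + π_Aπ_G/π_R`, `B = π_Cπ_T + π_Aπ_G` and
  `C = π_Rπ_Y` computed from empirical base frequencies of the aligned
  pair, and P/Q the observed transition and transversion proportions. At equal
  frequencies this reduces to the Kimura two-parameter distance, which the
  tests verify against an independent closed-form evaluation. Saturated
  pairs (non-positive logarithm arguments, or a missing purine/pyrimidine
  class) are flagged undefined and excluded from summaries.

Each comparison is summarized by mean and sample standard deviation over
defined distances and ranked descending (ties broken by longer aligned
length, then name). Marker selection intersects the top-*K* spacers of
every comparison (default *K* = 25, clamped to table size) and keeps those
with focal-genome length ≥ 500 bp — variability and length both matter for
a usable marker.

The built-in pairwise aligner makes the package self-contained; an
external hook (`plastocomp.align.mafft_align`) lets users reproduce
numbers that depend on a specific multiple aligner. Published divergence
values are aligner-sensitive and comparable only at ~2 decimal places.

## Reference-assisted assembly

The pipeline re-implements the recruit → assemble → iterate design at desk
scale:

1. **Recruitment**: a read is kept when it shares ≥ *t* k-mers (default
   *t* = 2, *k* = 31) with any reference plastome, either strand. This
   separates plastome reads from nuclear/bacterial contamination, which is
   k-mer-disjoint for all practical purposes.
2. **Initial assembly**: a minimal double-stranded de Bruijn assembler.
   K-mers are counted canonically (strand-min); unitigs are maximal
   non-branching paths; an isolated simple cycle is emitted as a circular
   contig. Default *k* = 31 (odd, so no self-reverse-complementary
   k-mers) suits the simulated 100-bp reads; it is a flag. Contigs below
   `min_contig_len` (default 500 bp) are dropped. In a quadripartite
   genome the graph collapses the IR into one double-coverage unitig, so
   the expected initial assembly is three contigs.
3. **Iterative improvement**: copy numbers are estimated from coverage
   relative to the length-weighted median; candidate circular superwalks
   of the unitig adjacency graph using each unitig exactly its copy number
   of times are enumerated (the IR is walked twice, once per orientation).
   When several walks survive deduplication modulo rotation/strand — the
   two SSC orientation isomers always do — they are scored by read pairs
   whose concordance **differs** between candidates (orientation correct
   and insert within `n_sd` = 4 standard deviations of the library mean);
   the winner needs ≥ 2:1 discriminating support and at least `min_links`
   = 3 pairs, otherwise the assembly is left unmerged and reported
   ambiguous rather than guessed. If the graph admits no circular walk
   (coverage gaps), a fallback loop scaffolds by mate-pair links, extends
   contig margins by overhang consensus (majority base, ties broken
   lexicographically, stop below 2:1 support), merges ≥ 200-bp exact end
   overlaps, and circularizes a single scaffold whose ends overlap
   ≥ 200 bp.
4. **Validation**: reads are re-mapped (exact 31-bp seed plus bounded-
   mismatch extension, no indels; equally-best placements share depth
   fractionally) for per-base depth, and windows whose spanning-pair
   median insert deviates by more than `n_sd` standard deviations — or
   which are covered by reads but spanned by fewer than 3 concordant
   pairs — are flagged as anomalies. A deliberately misjoined scaffold is
   flagged at its breakpoints by the zero-spanning rule.

Resolving the SSC orientation requires pairs that span a full IR copy, so
the end-to-end tests use a 6.5-kb-insert mate-pair library against a 5-kb
IR. With inserts shorter than the IR the two flip-flop isomers (both of
which co-exist in living plants) are informationally indistinguishable
from read data, and the assembler reports the ambiguity instead of
choosing.

## Supermatrix construction

Plastome gene names are standardized, so ortholog grouping is name-based
through a small synonym table (psbN/pbf1, psbZ/ycf9, ycf12/psb30), with an
optional shared-k-mer screen that flags (never auto-corrects) dubious
assignments; `infA` and `ycf15` are excluded by default as frequently
absent across asterids. IR duplicates collapse to one copy; two same-named
non-identical loci in one genome are reported as a conflict. Retained
groups (≥ 4 members, length ratio ≤ 10) are aligned — equal-length members
pass through unchanged, otherwise a center-star progressive alignment
around the longest member with "once a gap, always a gap" merging, or any
user hook such as MAFFT — concatenated in alphabetical gene order with `?`
padding for absent taxa, and exported as relaxed PHYLIP, NEXUS with a
CHARSET sets block, or FASTA. Tree inference itself is external by design.

## Synthetic data: what it does and does not emulate

`make_plastome` builds LSC + IRb + SSC + IRa with IRa the exact reverse
complement of IRb, ~38% GC, non-overlapping genes (CDS/tRNA/rRNA, a subset
with introns, rRNA genes duplicated in the IR, optionally a gene
straddling JLB), guard bases making the planted IR exactly maximal, and a
background scrubbed of accidental threshold-passing SSRs so planted SSR
counts are exact. Defaults approximate a typical asterid plastome
(86/18/25 kb regions); tests and the acceptance script use smaller
architectures (21–60 kb) chosen so every run finishes in seconds while
preserving the structural features that matter (IR longer than k and the
paired-end insert, realistic spacer-length spread).

`make_genome_pair` mutates only single-copy intergenic spacers at planted
per-spacer substitution rates (the IR is untouched, mirroring its slow
evolution and preserving the rc identity), plants shared SSRs at
homologous positions in both genomes and unique SSRs in one, by segment
replacement so coordinates stay aligned, and records exact per-spacer true
p-distances computed from the final sequences. Indels are off by default
so closed-form distance checks are exact; a Poisson indel mode exists for
robustness tests only. `simulate_reads` samples insert-normal fragments
uniformly over the circle in FR orientation with optional uniform
substitution errors and AT-rich (25% GC) contaminant fragments emulating
phytoplasma co-extracted DNA, with per-read origin/strand/contaminant
truth labels.

Not emulated: realistic quality-score error profiles, indel sequencing
errors, structural variation, mitochondrial insertions, gene-sequence
divergence between genome pairs (genes are copied verbatim, so pair tests
say nothing about coding-region divergence), and base composition
heterogeneity along the genome. Passing the synthetic suite therefore
demonstrates algorithmic correctness under clean, fully specified
conditions — not robustness to every artifact of real sequencing data.

## Numerical and degenerate-input choices

* Alignment: first optimal alignment returned by Biopython's
  `PairwiseAligner` (deterministic); identity = identical columns over all
  alignment columns.
* Divergence on pairs with no gap-free columns is undefined, flagged and
  excluded from summaries; a single defined distance reports SD 0.
* SSR threshold maps must be ≥ 1; lowering any threshold can only add
  loci (monotonicity is a tested invariant).
* `partition_quadripartite` raises on adjacent IR copies (no single-copy
  region) instead of emitting empty intervals.
* Assembly is deterministic end to end: canonical k-mer iteration order,
  lexicographic tie-breaks in consensus, fixed walk enumeration order.
* Generator RNG: one `numpy.random.Generator` per call, seeded
  explicitly; identical (spec, seed) reproduce byte-identical outputs.

## Known limitations

* Exact-match IR detection misses IRs with even a single internal
  mismatch between copies (rare but possible in degraded assemblies).
* The mapper has no indel support; depth near true indel variation would
  be underestimated.
* Name-based ortholog grouping inherits annotation errors; the k-mer
  screen only flags them.
* The assembler targets clean, high-coverage organelle data; it is not a
  general-purpose assembler and has no error-correction stage beyond
  low-count k-mer filtering.
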