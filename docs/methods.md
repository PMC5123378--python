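# Methods

## The classification model

A candidate SNV at one site is scored from the two pileups (tumor, matched
normal). Read bases are treated as independent draws from a two-component
mixture over the alleles: with probability *f* the read samples the alt
allele, with 1 − *f* the reference, and the sequencer then reports the
sampled allele correctly with probability 1 − *e* or one of the three
other bases uniformly (*e*/3 each), where *e* = 10^(−q/10) from the phred
base quality *q*. Mapping quality is carried on each observation but does
not enter the likelihood; it acts only as an inclusion filter (see below).

Two log10 odds are computed:

* `LOD_T = ℓ_tumor(f̂) − ℓ_tumor(0)`, where `f̂` maximises the tumor
  likelihood. Because f = 0 is in the search set, `LOD_T ≥ 0`.
* `LOD_N = ℓ_normal(0) − ℓ_normal(0.5)`, comparing "no variant, all
  non-reference bases are noise" against "germline heterozygote". In the
  noiseless limit each clean reference read contributes exactly
  log10 2 ≈ 0.301; each alt read at q30 subtracts ≈ 3.18, so a handful of
  alt reads in the normal flips the verdict — which is precisely the
  failure mode of independent calling this filter addresses.

The decision proceeds in fixed order: *insufficient_depth* when the
filtered normal pileup has < 8 reads or the tumor < 14 (no likelihood is
computed); *not_detected* when `LOD_T < Θ_T`; otherwise *somatic* when
`LOD_N ≥ Θ_N` (Θ_N|dbSNP at known polymorphic sites) and *germline* below.
All comparisons are inclusive, so a score exactly at a threshold passes.

### Parameters

| parameter | default | units | role |
|---|---|---|---|
| Θ_T | 6.5 | log10 odds | tumor detection threshold |
| Θ_N | 2.2 | log10 odds | germline-rejection threshold at unknown sites |
| Θ_N\|dbSNP | 5.5 | log10 odds | stricter threshold at known polymorphic sites |
| min normal depth | 8 | reads | gate before any likelihood |
| min tumor depth | 14 | reads | gate before any likelihood |
| relaxed preset | Θ_T = 4.5, Θ_N\|dbSNP = 3 | — | sensitivity-oriented re-analysis |

Θ_N at non-dbSNP sites is not pinned down by the relaxed/default threshold
pairs that motivate this tool; 2.2 is the conventional value of the joint
caller this statistic originates from, and it is exposed as a plain
configuration field. Lowering any threshold can only grow the output, so
relaxed-mode results are supersets of default-mode results by construction
(and this is asserted property-style in the tests).

### Numerical choices

* All likelihoods are sums of log10 terms; at the ≤ few-hundred read depths
  this tool targets there is no underflow concern, and the log-space values
  agree with an exact (50-digit decimal, direct product) oracle to
  < 10⁻⁹ in the test suite.
* The error probability is clamped at 0.75 so that `1 − e ≥ e/3` always
  holds; below phred 2 a base call would otherwise be "more likely wrong
  than right", inverting the model.
* `f̂` comes from a grid search over {0, 0.01, …, 1.00} augmented with the
  empirical alt fraction; exact ties resolve to the smaller fraction. A
  grid is deterministic, trivially cross-checkable against the oracle, and
  accurate to ±0.005 in `f̂`, which perturbs LOD_T negligibly relative to
  the 6.5 threshold.
* Empty pileups have log-likelihood 0 (empty product); LOD_N of an empty
  normal is 0 and such sites are in any case removed by the depth gate.
* Pileup construction applies a base-quality floor of 5 and a mapping-
  quality floor of 1, and drops duplicate-flagged, secondary and
  supplementary reads, deletions/reference skips, soft-clipped positions
  and N bases. The depth gates are evaluated on the *filtered* pileup —
  the same stack of observations the likelihood sees. Overlapping mate
  pairs contribute two observations each (no de-overlap).

## Pipeline semantics

Candidates enter as the allele-aware set difference (chrom, pos, ref, alt)
of tumor-sample calls minus normal-sample calls. The LOD stage tags every
retained record with `lod_t`, `lod_n`, `f_hat` and both depths, and returns
a per-verdict tally so before/after counts are reproducible on any input.
Known-site status is allele-aware membership in the supplied sites file, or
a non-null variant ID. After the union with the joint caller's calls, the
functional filter keeps non-synonymous / stop-gain / stop-loss records
(records with no class annotation are removed but tallied separately) and
the population filter removes records with MAF strictly above 0.05 —
records with no recorded frequency are kept, since removal requires
positive evidence that a variant is a common polymorphism.

FASTQ QC trims 3′ bases below phred 20, then drops reads in which more
than 80 % of the remaining bases are below threshold (trim first, then
filter — so a read with a long low-quality tail is rescued by trimming
rather than discarded). The operation is idempotent.

## The simulator

`synth_reads` generates a uniformly random reference segment, tiles
error-free single-end reads of fixed length (default 100 bp) with uniform
random start positions to a target mean depth (default 80X), injects
substitution errors at a uniform per-base rate (default 10⁻³, matching the
q30 quality it stamps on every base), and finally flips each read covering
a designated site to the alt allele with probability equal to the site's
target VAF. Defaults mirror the benchmark conditions this package
reproduces: ~80X coverage, q30 bases, exome-like read length.

What it deliberately does *not* model: quality decay along the read, indel
errors, paired-end fragments, mapping ambiguity, strand bias, GC bias,
copy-number structure or subclonal phylogenies. Passing tests on this
generator therefore demonstrate the *statistical* behaviour of the
classifier under its own noise model — they do not certify performance on
real alignments, where mapping artifacts dominate the false-positive
budget.

`spike_in` edits an existing alignment instead: at each truth site it
rewrites the aligned base of `k = round-half-up(VAF × eligible depth)`
reads (minimum 1) chosen uniformly without replacement, leaving names,
qualities, flags and CIGARs untouched; eligibility applies the same
filters as pileup extraction so the realized VAF (reported per site,
within 0.5/depth of target) is exactly what the classifier will see.
`downsample` keeps whole read names with probability target/current via a
seeded hash, which preserves mate pairing without a second pass.
`split_sample` orders read names by a seeded hash and deals them
alternately into two disjoint halves whose union is the input — the
split-sample specificity design, where any "somatic" call between the
halves is a false positive by construction.

The packaged truth table (`data/artificial_tumors.tsv`) lists 25 spike-in
sites with three tumor VAF columns — low (0.02–0.26, 23 non-NA entries),
intermediate (0.5–0.86, 25), high (0.97–1.0, 25) — plus the matched-normal
VAFs (8 sites at 0.02–0.03, blank elsewhere). The parser reports whatever
a table contains; no column size is hard-coded.

## Benchmark protocol and problem sizes

The recovery experiment (`evaluation.spike_recovery`, also the acceptance
script) relocates the truth sites onto one synthetic contig at 1 kb
spacing, simulates a tumor/normal pair from a shared reference at 80X/q30
with 10⁻³ errors — the normal carrying the table's normal-column VAFs —
and classifies every truth site at default thresholds with all sites
treated as unknown. Because the matched normals are not perfectly clean, a
site can occasionally draw an alt-rich normal pileup and be (correctly,
given the evidence) rejected as germline; the experiment therefore reports
the modal somatic count over several seeds rather than a single draw. The
false-positive experiment scans a 100 kb pair with a permissive alt-count
caller (`scan_candidates`, threshold: ≥ 2 concordant alt reads) and counts
LOD-retained calls outside the truth set; at q30 error rates, roughly
a hundred candidate sites per 100 kb reach two alt reads but none
approaches LOD_T = 6.5, which needs about six concordant q30 alt reads.
Coverage titration runs the same caller over a 5–80X grid in 5X steps.
These problem sizes (tens of kb, 80X, ≤ 10 seeds) keep every experiment in
the seconds-to-a-minute range while leaving the per-site statistics at
full scale — depth, qualities and VAFs are exactly the study conditions,
only the genomic extent is trimmed.

## Known limitations

* Single-nucleotide substitutions only; no indels, MNVs or structural
  events.
* No modelling of tumor-in-normal contamination or copy-number-driven
  allele fractions; the germline alternative is a pure 0.5 heterozygote.
* No priors on somatic mutation frequency and no strand-bias, clustered-
  position or proximal-gap artifact filters — the classifier is meant to
  sit downstream of, not replace, a caller's artifact filtering.
* dbSNP handling is membership-based; population allele frequencies enter
  only through the single configurable MAF field.
* The simulator's idealised noise model (see above) bounds what synthetic
  benchmarks can claim about real data.
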