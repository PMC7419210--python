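# Methods

This note records the models, numerical choices, and open design decisions
behind `dupliconevo`, in the spirit of a statistical-software methods
appendix. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Coordinates and interval algebra

All intervals are 0-based half-open (BED semantics); 1-based inclusive
genome-browser coordinates are accepted on read via a flag. Merging
coalesces overlapping *and abutting* intervals — this matches the
"redundant sites merged to nonredundant regions" semantics, where two
book-ended donor calls describe one locus. RepeatMasker class strings are
reduced to {SINE, LINE, LTR, DNA, other} on the class token before the
first `/`; unrecognized classes map to `other` because `.out` dialects
vary.

`flanking_unique` implements the "nearest contiguous 10 kbp of unique
sequence" as a base-by-base walk outward from each block edge that skips
duplicated sequence and concatenates unique bases until the target length
is reached. The alternative reading — the nearest single gap-free 10 kbp
window — is stricter; the walk was chosen because it always yields a
defined flank when enough unique sequence exists anywhere outward, and the
collected segments' coordinates are all reported. A side that exhausts the
chromosome or the unique space is returned truncated and flagged, not
erroneous.

`overlap_elements` counts *distinct* repeat elements: an element spanning
two regions contributes one count. This is the counting rule behind the
repeat-enrichment statistic, and it is property-tested against an O(n·m)
brute-force oracle.

## Permutation enrichment

For each region set and feature, the null is built from `n_permutations`
independent placement sets: every region keeps its length and receives a
uniform start over all genome positions where it fits entirely inside one
segment of the allowed space (genome minus SDs, centromeres, telomeres,
gaps). Placements are chromosome-agnostic and may overlap one another;
this is the simplest null consistent with an exclusion-set-only
specification. A per-chromosome placement mode is available by flag.

Aggregates: GC is the unweighted mean of per-region GC fractions (a
base-pooled mode exists); SINE/LINE use the distinct-element total. The
enrichment coefficient is E = observed / mean(null). Significance:

* SINE/LINE — Z-score transform of the permutation null,
  `p = Phi_bar((obs − mean)/sd)`, one-tailed in the enrichment direction
  (a depletion mode exists). The Monte-Carlo rank p agrees with the
  transform within a factor of ~3 whenever the null is near-normal and
  p > 1e-3 (property-tested).
* GC — two-sample Kolmogorov–Smirnov between the observed per-region GC
  values and per-region values pooled across all permutations (subsampled
  to 1e5 with the run seed), asymptotic p. Which null sample enters the KS
  test is not fully pinned down by the source description; pooling across
  permutations is the choice made here, and the Z-transform p is reported
  alongside in the output for comparison.

Bonferroni correction multiplies by |region sets| × |features| (nine for
the canonical 3 × 3 design) unless overridden. Each raw p carries
`SE = sqrt(p(1−p)/n)` with n the number of regions in its set, and a
result is flagged significant when corrected p + SE ≤ 0.05. The published
± values for the donor (n = 63) and pre-integration (n = 13) rows
reproduce exactly at printed precision; the acceptor row's printed ±
values are consistent with n ≈ 55 rather than the printed 27 (or the 37
redundant sites), so n is an explicit parameter here and the acceptor
discrepancy is documented rather than guessed at.

Very small p values from the normal tail are reported at float precision
in scientific notation, never truncated to zero.

## Junctions, deletions, and clone screens

Junction classification uses a **closed** ±50 bp window around the
breakpoint: an element whose last base touches the window boundary counts,
matching the "precisely at the breakpoints" reading; the half-width is
configurable. A single SINE hit dominates the verdict even when other
repeat classes are present.

Pre-integration deletion size is the anchor span on the outgroup assembly,
`(anchor_end − anchor_start)/1000` rounded to 0.1 kbp. In the packaged
13-locus fixture this rule reproduces the printed deletion for 10 rows;
for four rows (two of them plausibly 0.1-kbp rounding differences, two
larger) the printed coordinate pair and printed size disagree, so the
fixture ships the printed sizes and the residuals are left visible — the
rule is validated on the rows where it holds and agreement is not forced.
The summary median treats the single no-loss locus (a precise integration)
as a 0-kbp deletion, which reproduces the printed 5.8-kbp median over 13
loci; the 12-locus alternative (5.85) is reported alongside. The mean
repeat content of the deleted spans recomputed from the fixture (72.2%)
differs from the 67.56% printed in the source table's note; the recomputed
value is what `deletion_summary` reports.

Clone-screen copy number is `n_clones / coverage`, reported as the range
over the coverage bounds with a rounded-midpoint integer point estimate.
Only the "more than 15 copies" style bound is treated as reproducible; the
published integer copy numbers involve an unstated rounding convention.

## Modified Nei–Gojobori selection machinery

Potential sites weight each position's three single-base changes by a
transition/transversion ratio R: transitions get weight R/(R+1), each
transversion (1−R/(R+1))/2, renormalized per position after removing
changes to stop codons, so every codon contributes exactly three sites.
R defaults to 0.5, which reduces to the original unweighted method — the
source does not state the R it used — and the value is recorded in output.
Observed differences at multi-difference codons are averaged, unweighted,
over all orderings of single steps, excluding pathways through stop
codons; codons with no stop-free pathway are skipped and flagged. Both
operations are verified against exhaustive enumeration oracles over all 61
sense codons and random codon pairs.

Distances use the proportion or Jukes–Cantor correction (default JC), with
the standard large-sample variance `p(1−p)/(n(1−4p/3)²)` (or `p(1−p)/n`
uncorrected). The positive-selection test is one-tailed,
`Z = (dN − dS)/sqrt(var dN + var dS)`; the σ definition is not spelled out
in the source, and the analytic large-sample form is the standard choice
for this test family. A codon-bootstrap σ (1,000 resamples) is available
by flag. Gap/ambiguity handling deletes whole codons containing any
non-ACGT symbol, pairwise.

`group_selection_scan` runs all within-group pairwise comparisons per exon
of the partition (an excluded-exon set, by default the repeat-array exon
that defies global alignment, is dropped from output). How pairwise
comparisons were pooled into per-exon calls is not fully specified in the
source, so two summaries are emitted per row: a Z-test on pooled
difference/site counts and the mean of pairwise Z. Pooled counts over
pairs that share branches are not independent, so the calibration and
power properties are established on two-paralog groups, where the pooled
test is a plain two-sequence test; with larger groups the pooled Z should
be read as a descriptive ranking statistic rather than an exactly
calibrated test.

## Distance phylogenetics and timing

K2P: with transition/transversion proportions P and Q,
`K = −½ ln((1−2P−Q)√(1−2Q))`, delta-method standard error, pairwise
deletion of non-ACGT sites; a pair with a non-positive logarithm argument
is flagged saturated rather than given an infinite distance.

Neighbor joining follows the Saitou–Nei Q-criterion with deterministic
tie-breaking (lexicographically smallest pair of subtree-minimum labels);
negative branch lengths are clamped to zero with a warning and counted on
the tree. NJ reconstructs additive matrices exactly (property-tested on
random trees) and agrees topologically with an independent implementation
(scikit-bio) used purely as a cross-check oracle. Bootstrap supports
resample alignment columns with replacement, rebuild K2P + NJ per
replicate, and attach to each internal bipartition of the full-data tree
the fraction of replicates containing it; replicate trees are not
consensus-merged, and saturated replicates are skipped and discounted.

Tajima's relative rate test counts sites where exactly one ingroup
sequence differs from the other two (`m1`, `m2`) and refers
`(m1−m2)²/(m1+m2)` to chi-square with 1 df; `m1 + m2 = 0` is returned as
undefined rather than an error. Timing uses `R = K/2T` for calibration and
`T = K/2R` for dating; the round trip is exact by construction and tested
to machine precision. Default calibration points: chimpanzee–human
6–7 Mya, orangutan 15, macaque 25, and 35 Mya for the Old World monkey /
New World monkey split.

## Synthetic data: what it emulates and what it does not

The landscape generator produces blockwise-constant GC (default 50-kbp
blocks, mean 0.41, SD 0.05 — isochore-scale heterogeneity), and places
SINE/LINE/LTR elements by a per-block Poisson process at densities
approximating the euchromatic human genome (350, 150, 85 elements/Mbp).
Element lengths are fixed (SINE 300 bp, LINE 1 kbp — most genomic L1
copies are heavily 5'-truncated — LTR 500 bp) because only counts and
positions matter to the enrichment statistics. `sine_gc_coupling`
multiplies SINE intensity in above-median-GC blocks (renormalized to keep
the genome-wide density fixed); overlapping elements are thinned greedily
so annotations never overlap. The exclusion mask is a few uniformly placed
segments per chromosome totaling the requested fraction.

The duplication-history generator plants donors so that the *expected*
SINE density at donor positions is `donor_enrichment_E` times the
allowed-space average, by mixing uniform placement with placement
restricted to high-GC blocks; the mixing weight is solved from the
realized per-block densities, so the planted coefficient is exact in
expectation. Insertion points for acceptor junctions are drawn in
SINE-free unique sequence (new insertions land in unique DNA), the two
junctions of an insertion are separated by the insertion length, and an
AluS is planted in a junction window with probability `junction_alu_prob`
(default 9/14). Deletions are lognormal in kbp (default median 5.8 kbp,
σ = 1 log-unit, matching the 3.4–80.1 spread of the observed table) with a
configurable precise-integration probability (default 1/13).

The codon simulator evolves each group member independently from a shared
root of uniform sense codons, per-site Gillespie jumps with rate κ for
transitions and a factor ω on nonsynonymous changes, stop codons excluded.
One branch-length unit is one expected substitution per codon, averaged
over the 61 sense codons at the configured (ω, κ) — an approximation that
drifts slightly as composition evolves, which is irrelevant to the
recovery tests that condition on realized divergence. `block_size_range_kbp`
defaults to the observed 150–380 kbp span of real duplication blocks;
desk-scale analyses pass smaller blocks so that tens of donors fit a
tens-of-megabases genome.

None of the generators attempt real chromosome architecture, gene content,
gene conversion, or lineage-correlated duplication histories. Passing
tests therefore demonstrate that the statistics recover *planted* effects
under their own model assumptions — not that the biological conclusions of
any particular dataset follow.

## Problem sizes and stochastic tolerances

The planted-enrichment check uses 8 chromosomes × 5 Mb, 80 donors of
20 kbp, and averages E over eight independently simulated histories at
1,000–2,000 permutations each: a single donor draw on a strongly
block-heterogeneous landscape carries ~10% placement noise, so the
mean over histories is the estimator of the planted coefficient. Donor
sparsity matters here: when donors cover a large fraction of a small
genome, the distinct-element union rule discounts clustered donors more
than the spread-out null and biases E downward by several percent; at the
chosen sizes the residual effect is within the stochastic tolerance.
Type-I calibration runs 200 homogeneous landscapes at 250 permutations and
accepts a rejection rate within the 99% binomial band around 5%. ω
recovery pools substitution counts over 50 replicates of 300 codons at
0.1 substitutions/codon per branch; power (ω = 3) and size (ω = 1) of the
selection test use 100 and 300 two-paralog replicates at 0.125. Bootstrap
checks use 2,000-bp five-taxon alignments and 500 replicates. All checks
run in seconds to a couple of minutes on one CPU.

## Pipeline and reproducibility

`run_pipeline` executes simulate → enrich → junctions → selection →
phylogeny/timing from a flat key-value configuration, derives one named
RNG substream per stage from the single run seed, and writes a manifest
with config snapshot, substream seeds, per-stage wall time, and SHA-256
checksums of every output; identical configuration and seed reproduce
byte-identical outputs. CLI exit codes distinguish configuration (2), data
(3), and runtime (4) errors.

## Known limitations

* The permutation null treats regions independently; it does not condition
  on inter-region spacing or chromosome of origin (except in the optional
  per-chromosome mode).
* The Z-transform empirical p assumes an approximately normal permutation
  null; for very small region counts the Monte-Carlo rank p is the safer
  quantity and is available from the null object.
* The NG estimator's unweighted pathway averaging undercounts
  nonsynonymous steps when selection is strong, giving a few percent
  downward bias in ω̂ at ω = 3 and moderate divergence (visible, and
  within tolerance, in the recovery checks).
* Saturated pairs (K2P or JC) are flagged, not imputed; trees cannot be
  built over them.
* Bootstrap supports refer to the full-data topology only.
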