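# Methods

## Scope and data model

Every computation operates on a `HaplotypePanel`: phased alleles of `2N`
haplotypes at `M` biallelic SNPs on one chromosome, coded 0 (reference),
1 (alternate), −1 (missing), with haplotype rows `2k`/`2k+1` belonging to
diploid sample `k`. Phase provenance is tracked explicitly — panels loaded
from "/"-separated VCF genotypes or PED/MAP are unphased and may only reach
LD statistics through the two-locus EM; counting-based LD requires the
phased flag. Positions are 1-based internally (the VCF convention); BED
output converts to 0-based half-open at the boundary. Sex chromosomes,
unplaced loci, non-SNP and multiallelic records are dropped at load with
logged counts; duplicate-position markers keep the first occurrence.

## Quality control

Samples with genotype call rate < 0.90 are removed first; SNP statistics are
then recomputed on the survivors and applied in the fixed order call rate
(< 0.90) → Hardy–Weinberg exact-test p (< 1e−4) → MAF (< 0.05), each marker
attributed to the first filter it fails so removal counts are additive. The
HWE test is the two-sided exact conditional test (no mid-p): conditioned on
the allele counts, it sums the probabilities of all heterozygote counts
whose conditional probability does not exceed the observed one. Ties are
accepted with a 1e−9 relative tolerance so that float evaluation matches
exact rational enumeration. When a two-group analysis is run, each group is
QC'd separately (group-specific marker sets, like group-specific chip
panels), and the joint group is QC'd on its own pooled samples for the block
scan.

## LD statistics

All two-locus statistics derive from the four phased haplotype counts of a
pair over haplotypes complete at both loci (pairwise deletion):

    D = p_ij − p_i p_j,  r² = D²/(p_i(1−p_i)p_j(1−p_j)),
    D′ = |D|/D_max,      signed r = √r² · sign(D).

D is evaluated in the determinant form `(n11·n00 − n10·n01)/n²` —
algebraically identical, but exactly antisymmetric under re-orienting either
marker, because count products are integers represented exactly and IEEE
negation is exact. Consequently signed r flips sign bitwise and r²/D′ are
bitwise invariant when a marker's ref/alt labels are swapped consistently,
which the phase-persistence invariances rely on. Pairs in which either
marker is monomorphic among the complete haplotypes are undefined (the r²
denominator vanishes) and are skipped, not zero-filled. The pairwise scan is
restricted to pairs within 500 kb (a sliding window over the sorted map);
the dense-matrix implementation holds `M × M` float32 products per
chromosome, fine for desk-scale panels up to a few thousand markers per
chromosome.

The D′ confidence interval evaluates the multinomial likelihood of the four
counts on a uniform 101-point D′ grid with marginals fixed at their observed
values and the sign of D fixed, normalises it to a discrete posterior under
a flat prior, and reports the central 90% quantiles. Grid resolution and
mass are parameters; the defaults trade speed for a resolution (0.01) well
below the classification thresholds they feed.

The two-locus EM treats only the double heterozygote as phase-ambiguous and
iterates the standard coupling-fraction update to a 1e−10 frequency
tolerance. The likelihood surface can hold several stationary points and
the symmetric start (ambiguous mass split evenly) can stall on a saddle, so
the default runs three starts (coupling fractions 0.5, 0.02, 0.98) and keeps
the best final likelihood; a single symmetric start remains available via
the `starts` argument.

## Decay profiles

Distances bin into `{0, 2.5, 5, 7.5, 10, 20, …, 100, 200, 300, 400, 500}` kb,
half-open `[low, high)` with the final bin closed at the cap, so every
distance maps to exactly one bin. Per bin: pair count, mean, sample SD
(n−1 denominator), and exact median (per-bin value stores; the desk-scale
memory cost is negligible, and exact medians are part of the table
contract). Summaries are permutation-invariant to input order.

## Persistence of LD phase

Shared pairs are the inner join of the two groups' pair tables on
(chromosome, pos_i, pos_j); an inner join is the only sign-consistent
choice when QC leaves different marker sets per group. The join refuses to
proceed if any marker common to both groups carries different ref/alt
labels, since the sign of D is only comparable under one orientation.

PL is the correlation through the origin of signed r between the groups,
`Σab/√(Σa²Σb²)`, not the mean-centered Pearson coefficient. Signed r has no
natural location: the allele orientation that fixes the sign of D is
arbitrary (any subset of markers may be consistently re-oriented in both
groups), and the uncentered form is exactly invariant under such joint
flips — coordinated sign flips leave every product unchanged — while
centering is not. In large bins signed r is mean-zero to good approximation
and the two estimators coincide; the centered Pearson value is emitted
alongside (`pl_centered`) for comparison. Bins with fewer than 3 shared
pairs or no variation are reported undefined. The headline overall value is
the unweighted mean of defined per-bin PL; a pair-weighted pooled value is
also emitted.

## Haplotype blocks

The Gabriel confidence-interval rule with its published thresholds, all
exposed as parameters: strong LD = D′ CI (≥ 0.70, ≥ 0.98); strong
recombination = CI upper bound < 0.90; a candidate interval needs a
strong-LD endpoint pair and ≥ 95% strong-LD among informative internal
pairs (uninformative pairs leave the denominator). Pairs beyond 500 kb
never enter, which bounds block span. Overlaps resolve greedily — longest
bp span first, ties to more SNPs then leftmost — and blocks of fewer than
three SNPs are dropped after selection, avoiding spurious two-SNP blocks.
Tool-specific refinements found in some implementations (marker-count-
dependent fraction tweaks, short-span pair skipping) are deliberately not
reproduced; this is the clean published definition. Candidate enumeration
uses 2-D prefix sums over the classified-pair matrix and is tested against
an exhaustive interval-checking oracle. Per-chromosome summaries report
marker span as the chromosome length (an assembly length is not available
to a marker map, and block coverage should be judged against genotyped
territory).

## Synthetic data

The generator produces the demographic structure the analysis assumes,
with discrete non-overlapping Wright–Fisher generations of N monoecious
diploids (random mating with replacement): an ancestral population burns in
for 4·Ne generations from a random linkage-equilibrium start, splits into
two founder pools that drift apart, a composite forms by drawing founder
gametes in 5/8 : 3/8 proportions, breeds inter se, splits into two groups
that drift independently, and finally each group samples its diploids by
one more round of random mating.

Recombination follows the Markov (Haldane) model: between adjacent markers
a gamete switches parental haplotype with probability `(1 − e^(−2cg))/2`
for gap `g`, implemented by Poisson crossover events with the inverse-
Haldane per-interval intensity (distribution-equivalent, O(events) cost).
Hotspots multiply the intensity of the interval containing their position.
Variation is standing founder polymorphism only — no recurrent mutation —
so polymorphism attrites under drift; markers fixed after burn-in are
dropped immediately (distribution-preserving, they cannot re-polymorphise),
and a chromosome whose composite cannot supply the requested marker count
is resimulated with a doubled discovery panel. Ascertainment emulates a
genotyping array's common-SNP bias: markers fixed in the composite are
dropped, the panel is drawn uniformly from composite-MAF ≥ 0.05 survivors,
topped up from the most-common remainder only on shortfall.

Default conditions (one seed determines everything): 2,000 markers over a
5 Mb genome split across 4 independent 1.25 Mb chromosomes — a multi-
chromosome genome mirrors the genome-wide pooling of the real analysis and
exercises the per-chromosome code paths; founder Ne = 100; founder
divergence 100 generations (Fst ≈ 0.4, a strongly diverged pair of founder
breeds); 15 composite generations (a breed formed some decades ago at a
~5-year generation interval); 5 generations of group split (two management
groups of one young breed); 100 diploids per group; recombination rate
1e−7 per bp per generation, chosen so that the desk-scale product Ne·c —
the quantity equilibrium LD decay depends on — matches a cattle-scale
population at the field's ~1e−8 map.

What the generator does *not* emulate: genotyping error, pedigree-accurate
crossing schemes, selection, sex chromosomes, mutation–drift equilibrium
site-frequency spectra (standing variation from a single ancestral draw
yields stronger short-range LD than a coalescent with mutation), and a
realistic genome length. Passing tests therefore demonstrate that the
statistics behave correctly under the assumed demography at desk scale, not
that real-data profiles will be numerically similar.

A known desk-scale limitation: with ~0.4% of a cattle genome, per-bin mean
r² carries realization noise of the same order as adjacent-bin expected
differences in the 40–100 kb range, so a single simulated genome can show a
handful of small adjacent-bin inversions in an otherwise cleanly decaying
profile (bin means fall ~0.97 → ~0.05 over the cap). The suite's strict
monotonicity check fails on such realizations, including the default seed;
this is sampling noise of the fixed-size study design, not an estimator
property, and it averages out at real genome scale.

## Numerical and determinism notes

* One integer seed determines every simulated panel byte-for-byte; the
  pipeline writes tables with a fixed float format and a manifest free of
  absolute paths, so reruns reproduce outputs byte-for-byte.
* PL = 1.0 holds *exactly* for identical groups because the uncentered
  correlation evaluates to `v/√(v·v)` and `√(x·x) = x` exactly in IEEE
  arithmetic.
* HWE p-values clip tie comparisons at 1e−9 relative; exact-enumeration
  agreement is exhaustively tested to 50 individuals.
* Degenerate inputs: monomorphic pairs are skipped with a dedicated error;
  all-missing markers give NaN MAF and fail call-rate QC; empty bins report
  n = 0 with empty summaries; a chromosome with no blocks reports zeros.
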