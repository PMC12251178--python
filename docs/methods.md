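# Methods

## The model

The simulator is a discrete-generation Wright–Fisher model of two
asexually reproducing strains sharing one niche at constant joint census
size N. The population is partitioned into lineages, each a triple
(marker id, relative fitness, count); four founder lineages carry the
neutral fluorescent markers at initial fractions (0.05, 0.05, 0.45, 0.45)
— markers 0 and 1 belong to the low-abundance strain A (10% of the
population), markers 2 and 3 to the resident strain B1 (90%). Founders
start at fitness exactly 1.

Each generation:

1. **Mutation.** Every lineage yields Binomial(count, u) beneficial
   mutants. Each mutant founds a new lineage with fitness
   w_parent · (1 + s); the parent loses that individual. Effects s are
   drawn from the configured DFE: `fixed` (all draws equal the mean s̄) or
   `gamma` with shape k and scale s̄/k, so the mean is s̄ independent of
   shape. Shape 1 is the exponential DFE; shape 100 is numerically close
   to the fixed-effect limit. Fitness across multiple mutations in one
   lineage composes multiplicatively — the standard convention; it keeps
   fitness positive and is order-independent.
2. **Resampling.** The next generation's counts are one multinomial draw
   of size N with probabilities ∝ count × fitness. Census conservation is
   therefore exact, and zero-count lineages are pruned.

Mutation precedes resampling, so a mutant arising in generation t can be
sampled (or lost to drift) in generation t+1. The reverse order is
statistically indistinguishable at the parameter scales used here
(u ≤ 10⁻⁴), differing only in whether a mutant can be lost in the same
generation it arises.

The model deliberately excludes recombination, gene transfer between the
strains, deleterious mutations and frequency-dependent effects; it is a
null model of directional selection with clonal interference only.

### Outcome classification

A finished replicate is scored against the experimentally observed
pattern. A marker is *maintained* when its final within-strain frequency
is ≥ 0.001 (default; configurable, 0 = strict extinction). Rationale: CFU
plating cannot resolve rarer lineages, and strict extinction is nearly
unreachable at N = 10⁶ within 1600 generations under weak selection, which
would make simulated "loss" incomparable with the plating-based
experimental calls. A strain is *extant* when its final share of the
total population is ≥ 0.01; the pattern being matched is a coexistence
pattern, so a replicate that loses a strain is incompatible. *Compatible*
= both strains extant, A maintaining exactly one marker, B1 maintaining
two.

### Parameter sweep

The grid crosses log-spaced u ∈ [10⁻⁸, 10⁻⁴] and s̄ ∈ [10⁻⁴, 10⁻¹] with
DFE shapes {fixed, 100, 10, 1}, 10 replicates per cell by default (the
default 5 × 4 × 4 grid bounds desk runtime; full-resolution grids go
through the config). Per cell, a two-sided Fisher exact test compares the
simulated compatible/incompatible split with the experimental one (8 of 8
co-colonized mice); cells with p > 0.05 ("starred") are statistically
indistinguishable from the data. The test is per-cell; pooling across
cells was considered and rejected as it conflates parameter sets.
Replicate r of cell c is seeded `base_seed + c·replicates + r`, so every
replicate in the grid has its own reproducible stream and no two cells
share one.

`fisher_exact_2x2` delegates to `scipy.stats.fisher_exact`; the test
suite validates it against an independent brute-force hypergeometric
enumeration for all tables with margins ≤ 20.

## Marker-trajectory analysis

Plating has a detection limit (default 300 CFU/g feces). A zero count is
treated as "below LOD", not as proven absence: its within-strain
frequency is reported as the upper bound LOD/(LOD + CFU_other). Marker
polymorphism is called *lost* for a (mouse, strain) when the same single
marker is below LOD on the last k = 2 sampled days (k configurable); one
noisy day should not trigger a loss call, and the experiment's loss calls
are terminal-state judgments. A strain absent (both markers below LOD) on
every sampled day from day 7 onward is *not colonized* — day 7 separates
colonization failure from later extinction. The strain-dependence of
polymorphism maintenance is tested with a two-sided Fisher exact test on
the maintained/lost 2×2 table (not-colonized mice excluded). Load
summaries average log10 total CFU per mouse over coexistence days (both
strains ≥ LOD), then take mean and SE across mice.

## Variant-table analytics

Coordinates are 0-based half-open throughout; conversion happens only at
I/O boundaries. The ancestral false-positive filter blacklists ancestral
variants with frequency strictly above 0.015 *and* strictly more than 3
supporting reads, plus all ancestral consensus-mode calls, and removes
evolved variants matching the blacklist by site. Sweeps use strict
frequency > 0.95; frequency 1.0 is additionally flagged fixed. dN/dS is
the raw count ratio of non-synonymous to synonymous SNPs (no
substitution-model correction), undefined when S = 0. M(t) sums detected
allele frequencies per mouse and divides by elapsed generations
(days × 18); mice with no retained variants contribute 0, and means use
only successfully co-colonized mice.

Element presence from coverage uses the median depth of the element
region divided by each flank's median depth, averaged over the two
flanks; the raw ratio is retained and the reported value clipped to
[0, 1]. Flank size defaults to 5,000 bp per side — wide enough to be
robust to local depth noise at 100×, narrow enough to stay clear of
neighboring copy-number features.

The HGT read rule considers reads overlapping a variant site; a read
"matches" a reference iff it equals the reference substring over its full
span exactly (forward or reverse complement). This is the decision-rule
stand-in for a 100%-identity alignment: since only perfect matches count,
a full local aligner adds nothing. Reads matching both references are
ambiguous and count for neither. A variant is flagged when the
donor-matching fraction strictly exceeds 1%. Flagged variants within a
configurable gap merge into half-open tracts; endpoint resolution is one
read length plus the local spacing of diverged sites.

## Fitness assays

Growth rate: readings with OD ≤ blank are excluded (their log is
undefined), then every window of 5 consecutive retained points is fit by
OLS on ln(OD − blank) vs time; the maximum slope among windows with
R² > 0.9 wins, ties to the earliest window. Windows slide (overlap)
rather than tile — tiling would make the estimate depend on an arbitrary
phase. The blank is a single scalar per curve; plate-level blank
averaging is the caller's responsibility. Carrying capacity is
max(OD − blank, 0).

Selection coefficient: per mouse, OLS slope of ln(CFU_focal/CFU_ref) on
day; days with a zero count are dropped with a warning (a zero CFU makes
the ratio undefined and usually reflects the detection limit). The pooled
estimate is the mean of per-mouse slopes with SE = SD/√n; per-generation
values divide by 18 generations/day and are reported to two decimals,
matching the printed precision conventions (means to one decimal, rates
to two significant digits, all rounding half away from zero).

## Synthetic data: what it emulates and what it does not

Generators are deterministic given (config, seed) and every generator
emits a truth table (`truth_`-prefixed columns) that recovery tests
consume. Defaults are the study conditions: 8 mice, strain loads 10^8.5
and 10^7.4 CFU/g with between-mouse log10 SD 0.4 (the printed SE scale),
LOD 300 CFU/g, 12 sampling days over 88 days, per-strain event-class
mixes matching the observed breakdowns (82 and 38 events across 8 mice),
2% reference divergence (within the observed 80–100% per-100-bp identity
band), logistic growth at r = 1.08 h⁻¹, and a competitive index rising at
4.0/day.

Trajectories in parametric mode plant the experimental pattern directly
(strain A loses one marker from day 43 on); in simulator mode the
within-strain splits come from Wright–Fisher replicates at 18
generations/day. Ground-truth status labels apply the same call semantics
(below-LOD on the last two days; absence from day 7 onward) to the
pre-detection-limit values, so truth and classifier disagree only through
the detection limit itself.

Not emulated: instrument-specific sequencing error profiles, read mapping
artifacts, chimeric reads at tract boundaries, within-day load dynamics,
plasmid copy-number evolution, and real microbiota context. Passing
recovery tests therefore demonstrates correctness of the estimators under
the stated noise models, not robustness to raw-sequencing artifacts —
those are handled upstream by the standard callers whose table-shaped
outputs this package consumes.

## Numerical choices and problem sizes

- RNG: one `numpy.random.Generator` (PCG64) per replicate; the pipeline
  expands a single global seed with fixed stage offsets (synth +0,
  simulate +1000, sweep +2000).
- Largest-remainder apportionment seeds founder counts that sum exactly
  to N; ties break by index order.
- Frequencies are exact rationals count/N stored as floats; snapshot
  spacing defaults to 18 generations (one day).
- Closed-form oracle tests use N = 100 with 3000 replicates
  (heterozygosity decay (1 − 1/N)^t) and N = 1000, s = 0.02 with 2000
  replicates (logistic selection recursion) — sizes where Monte-Carlo SE
  is small but second-order Jensen bias of the nonlinear recursion is
  negligible.
- The DFE-shape comparison runs 30 replicates per DFE at N = 10⁶,
  g = 1600, u = 10⁻⁵, s̄ = 0.01: enough replication that the strict
  ordering (fixed and shape-100 above exponential) is stable across seeds
  while one full replicate costs ~0.1 s.

## Known limitations

- The loss/extinction thresholds (0.001 within strain, 0.01 total) are
  classifier conventions, not biology; conclusions near those thresholds
  should be checked for sensitivity.
- `classify_polymorphism` cannot distinguish late strain extinction from
  maintained polymorphism when both markers vanish simultaneously after
  day 7 (it reports "maintained" since no single marker was lost); the
  experimental design this mirrors had no such case.
- The HGT rule's exact-match criterion is conservative under sequencing
  error: an erroneous read matches neither reference, which depresses
  both match fractions equally but lowers power at low donor fractions.
- dN/dS as a raw count ratio is not comparable across genes with very
  different synonymous target sizes.
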