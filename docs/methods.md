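# Methods

This note documents the models implemented in `admixscan`, the defaults and
why they were chosen, what the synthetic data does and does not emulate, and
the numerical choices that make runs bit-reproducible.

## Local-ancestry model and gene counting

The unit of data is a haplotype partitioned into ancestry tracts
(0-based half-open coordinates, a constant 1 cM/Mb map imputed when a file
carries no genetic positions). Adjacent same-ancestry windows are merged on
read, so tract identity is canonical and round trips through the msp dialect
are exact. Calls below a confidence threshold are carried as the code −1
(UNASSIGNED) rather than dropped from the file, so coverage bookkeeping
stays exact.

A haplotype counts toward a gene only when a single assigned-ancestry tract
covers the whole gene interval; a switch or an unassigned segment inside the
gene removes the haplotype from both `h_anc` and `h_tot`. This strict rule
reproduces the gene-to-gene variability in `h_tot` that the downstream
filter presupposes, and is verified against a per-base enumeration oracle on
random toy panels.

## The scan and its filter

`z_anc = (f_anc − μ_anc)/σ_anc`, with μ and σ the mean and sample
(n−1 denominator) standard deviation of gene-level fractions over *retained*
genes: those with `|h_tot − μ_htot| ≤ σ_htot`. The filter wording is read
conservatively: a gene must pass in **every** population to enter the
combined analysis. One-sided normal p-values are combined separately for
enrichment and depletion — combining two-sided p-values would let
opposite-direction signals in different populations reinforce each other,
which contradicts the cross-population concordance the screen looks for.
Ancestries with σ = 0 (e.g. an ancestry absent from a population) are
flagged undefined and skipped with a warning rather than raised, so one
degenerate component does not abort a genome scan.

The normal approximation for gene-level `f_anc` is adequate at the default
cohort sizes (h_tot ≈ 200): the neutral-cohort rejection rate at α = 0.05
stays inside the 99% binomial band (checked in the acceptance suite). An
exact binomial alternative was deliberately not substituted, as the z-based
formulation is what the combined score and the PAE statistic build on.

## Synthetic cohorts

`synthetic_data` implements the pulse-admixture tract model: breakpoints are
a Poisson process of rate g per Morgan (g = generations since admixture,
default 10), tract ancestries i.i.d. from the population's genome-wide
fractions θ. This gives closed-form expectations used by the tests: merged
tract genetic lengths are exponential with rate g·(1 − Σθ²), and the local
ancestry fraction equals θ everywhere.

Injected enrichment raises the target ancestry's tract probability to
`f_target` inside a chosen interval, rescaling the others proportionally.
Tract boundaries are forced at the interval edges so that every position
inside the interval has expected target fraction exactly `f_target` and the
signal does not bleed outward through long tracts; the Poisson breakpoint
density is otherwise untouched.

What the generator does **not** emulate: linkage between ancestry and
genotypes (there are no genotypes), realistic recombination-map
heterogeneity (constant map by default), pedigree-structured tract length
correlations (tracts are i.i.d. given breakpoints — the Wright–Fisher
simulator provides the mechanistic alternative), and reference-panel or
phasing error beyond the uniform per-tract UNASSIGNED relabelling. Passing
tests on synthetic cohorts therefore validate the statistical machinery,
not the upstream local-ancestry inference.

Two demo-specific choices matter for interpretation:

- **Unassigned calls are off in the demo cohort.** Per-tract UNASSIGNED
  relabelling is correlated over multi-megabase tract blocks, so with u > 0
  the `h_tot` filter can drop an entire region in one population by chance,
  which makes a planted single-locus signal irreproducible across seeds.
  The relabelling mechanism is exercised and calibrated in its own tests;
  the demo simply runs at u = 0 so that retention noise is fine-grained.
- **Random trait sets avoid injection intervals in the demo.** They serve as
  negative controls; a "random" set containing planted-signal genes is a
  true positive and would be reported as such.

The four demo populations share an African fraction of 0.25 with distinct
European/Native American mixes — package defaults chosen to represent a
realistic Latin American admixture scenario, not estimates from any cohort.

## Null simulations

The gene-wise multinomial null redraws each gene's `h_tot` haplotypes from
θ and restandardizes z within each replicate, mirroring the observed
pipeline exactly; this keeps the null self-contained and exchangeable with
the observed statistics. Empirical p-values use the add-one estimator
`(1 + #{null ≥ obs})/(1 + R′)`, which never returns 0; a `max_statistic`
mode pools each replicate's genome-wide maximum for family-wise control.

The Wright–Fisher simulator uses monoecious random mating with selfing
allowed (both parents drawn uniformly with replacement — the standard WF
convention, stated here because "chosen to mate" admits variants), founding
composition by largest-remainder rounding of N·θ, crossover counts Poisson
in the map length with no interference, crossover positions uniform on the
genetic map, and a random starting haplotype per meiosis. Gametes are exact
tract partitions at every generation; bp positions are rounded from genetic
positions at output, with sub-bp segments absorbed into their neighbours.

## PAE

The permutation universe is the retained genes with defined z in the same
population — permuted sets must be exchangeable with the observed set under
the scan's filters, so genes the scan never scored are excluded. Null
moments depend only on (population, ancestry, set size) and are cached;
their exact finite-population values (mean k·z̄, variance
k·S²·(m−k)/(m−1)) anchor the tests. Significance is the two-sided normal
p of z_PAE, with the empirical rank p reported alongside; FDR families are
per (population, ancestry). Consensus requires the same ancestry **and**
direction in ≥ 2 populations. Genotype-based LD pruning is out of scope;
`distance_prune_geneset` (default minimum gap 250 kb) is the coordinate
proxy, and pre-pruned GMT files are accepted as-is.

## Selection model

Genic (multiplicative, haploid-equivalent) selection on the favored
ancestry haplotype, the other two selectively equivalent: with favored
frequency p, `p′ = p(1+s)/(1+sp)`. This is the minimal standard recursion
for haplotype-frequency dynamics; it satisfies the closed form
`p_t/(1−p_t) = (1+s)^t · p₀/(1−p₀)`, which the implementation must match to
1e−10. Trajectories start from the genome-wide background fraction
(p₀ = μ_anc unless overridden), and the observed-scan σ_anc puts model
output on the same z scale as the scan. Default t = 20 generations (a
conventional admixture age for the Americas; the demographic null uses
g = 10 as a lower bound) — both are parameters, not claims. `infer_s`
inverts the strictly monotone s ↦ z map with Brent's method (xtol 1e−8) on
s ∈ [0, 1] and raises, naming the achievable interval, when z is out of
range. The estimate is an upper bound: all observed deviation is attributed
to selection at that locus.

## Numerical and reproducibility choices

- Single global seed; per-stage seeds derived as
  `(seed·1000003 + crc32(stage)) mod 2³¹`, so stages have independent
  streams and are individually reproducible.
- All tables are TSV with fixed headers; reruns with the same config are
  byte-identical (verified in tests).
- p = 0 in a combination is an error (log of zero) rather than silently
  clamped; undefined cells propagate as NaN with warnings collected in the
  run manifest.
- Degenerate inputs: σ_anc = 0 ancestries are flagged, empty gene universes
  and empty GMT sets are errors, N = 2 Wright–Fisher populations and g = 0
  are supported boundaries.

## Problem sizes in the shipped checks

The acceptance suite and `scripts/acceptance.py` use cohorts of 4 × 100
diploids with 200 genes; the neutral-calibration cohort spreads its genes
over a 20-Morgan span so gene-level scores are nearly independent, the way
a genome-wide gene panel behaves (on a single short chromosome, shared
tracts correlate neighbouring genes and any calibration statement would
need an effective-sample-size correction). The Wright–Fisher diagnostics
use 10⁴ gametes, 100–200 replicates at N = 100, and a single N = 10,000
contrast; the end-to-end demo check repeats the full screen across 50
seeds. These sizes were chosen so that every Monte-Carlo tolerance in the
tests is set by the statistic's own standard error.

## Known limitations

- No genotypes anywhere: iHS-style statistics are consumed as external
  score tracks, never computed.
- The recursion models a single selected locus per fit; interacting selected
  loci and dominance are out of scope (the genic model is the configurable
  default, not an inference about the true architecture).
- The h_tot retention filter is a hard threshold; near-degenerate `h_tot`
  distributions (as in the u > 0 note above) make retention effectively
  random near the boundary.
- Empirical p-values are bounded below by 1/(pool + 1); genome-wide claims
  at 5 × 10⁻⁵ need pools of ≥ 20,000 null values.
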