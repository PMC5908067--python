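# Methods

## Model

`reefadapt` simulates discrete, non-overlapping Wright-Fisher generations in
a set of populations connected by migration. The trait under selection is an
individual's thermal optimum (°C), controlled by `n_qtl` unlinked loci with
continuous allelic effects.

**Genetics.** Each haplotype stores one real number per locus (continuum of
alleles): a new mutation adds an N(0, `effect_sd`) increment to the existing
allelic value, so the representation carries the full mutational history in
O(N·L) memory without tracking mutation objects. Gametes segregate freely —
one of the parent's two allelic values per locus with probability ½ — and
mutate with probability `mut_rate` per locus per gamete. Free recombination
is an idealization: with 10–100 loci scattered in a ~500 Mb genome, linkage
between any particular pair is weak, and it makes every per-generation step a
dense vectorized array operation. The breeding value is the sum of allelic
effects over loci and haplotypes. Dominance h enters per locus as
`a_min + 2h·(a_max − a_min)` with a_min/a_max the smaller/larger-magnitude
allele; at h = 0.5 this is exactly additive (the only setting exercised by
the shipped scenarios — how dominance should combine with stacked continuous
alleles is genuinely ambiguous away from 0.5, so other values are flagged
experimental).

**Selection and reproduction.** Phenotype = breeding value + N(0, `esd`)
noise; fitness w = exp(−(z − T)²/2σ²), an unnormalized Gaussian peaking at 1.
The peak-1 convention makes the reported "mean fitness relative to the
maximum attainable with perfect heritability" simply the mean of w. Parent
slots are drawn independently with probability ∝ w (selfing allowed —
hermaphroditic broadcast spawners). Note the curve implies an 86.5% fitness
drop at 1 °C mismatch for σ = 0.5, 39.3% for σ = 1 and 11.75% for σ = 2;
nominal round figures often quoted for these settings (86/40/13%) match to
printed precision except σ = 2, where 13% appears to be a rounding of the
same curve.

**Migration.** `rates[i][j]` is the probability that an offspring born in
destination j draws its parents from source i (source rows × destination
columns; the matrix is never transposed internally, and TSV import/export
keeps the same orientation). Migration happens at offspring creation, not by
swapping individuals. When a source's emigration is scaled down, the
destination's shortfall is reassigned to residents: a destination's census is
set by its own fitness, never by immigrant supply.

**Environment.** T[t, p] = base + offset_p + anomaly[t] + ramp. Anomalies are
i.i.d. N(0, `anomaly_sd`) shared by all populations within a generation (one
basin-wide ENSO-like draw; an independent-per-population mode exists behind
`shared_anomaly: false` but is off by default). Base temperature is 0 by
convention — the model is translation-invariant, so all temperatures are
anomalies relative to the mild-regime optimum. The ramp is linear at
`warming_rate` after the burn-in ends and the series is generated up front
for the whole run, so warming continues past extinctions. Anomalies apply
during the burn-in as well as the warming period.

**Demography.** Fitness-dependent demography activates `demography_lead`
(default 500) generations before warming onset and stays on: census_j =
round(base_j · clamp(mean_w_j / historical_j, 0, 1)), and the same clamped
ratio scales emigration. `historical_j` is the mean fitness averaged over the
100 generations preceding activation — a window, rather than a single
generation, so that anomaly noise does not contaminate the reference. Upward
scaling is clamped at 1 (carrying capacity). A census below 2 — the minimum
for biparental reproduction — is extinction; extinct populations never
recolonize. Whether reduced fitness should throttle only emigration or also
immigration is not decidable from the model description alone; we scale
emigration and renormalize the destination's parentage mix, which keeps a
healthy population's size independent of its neighbors' collapse.

**Burn-in.** The allele frequency spectrum depends on N·μ, and smaller
populations equilibrate proportionally faster, so standing variation is built
by stages: default 5,000 generations at 1/100 size and 100× mutation rate,
5,000 at 1/10 and 10×, then 10,000 at target values. Stage transitions
resize through the next Wright-Fisher draw (parents come from the old-size
pool), which preserves the allele-frequency spectrum shape in expectation;
nothing is duplicated. Config validation enforces a constant
mut_multiplier/size_divisor ratio across stages so N·μ is actually preserved.
The demography lead-in is taken as the final 500 generations of the full-size
stage, not appended after it.

## Parameters

| parameter | units | default | why |
|---|---|---|---|
| n_qtl | count | 10 | deliberately coarse architecture (conservative for adaptive potential) |
| effect_sd | °C | 0.2 | new-mutation effect SD; 100-QTL runs use 0.063 = 0.2·√(10/100) to keep n·a² fixed |
| mut_rate | per locus per gamete | 1e-6 | order-of-magnitude midpoint of realistic per-locus rates; 1e-7/1e-5 probe the ends |
| esd | °C | 1.0 | intermediate heritability; 0 = heritability 1 |
| sigma | °C | 1.0 | intermediate tolerance breadth; 0.5/2 probe narrow/broad |
| dominance | – | 0.5 | additive; the only exactly-defined setting for stacked continuous alleles |
| anomaly_sd | °C | 0.25 | ENSO-scale between-generation variability |
| warming_rate | °C/gen | 0.05 | 0.1 °C per decade × 5-year generations |
| demography_lead | generations | 500 | fitness-dependent demography precedes warming |
| gen_time (conversions) | years | 5 | time to full reproductive output of a colony |
| mu_frac (conversions) | per 2bRAD fraction per gen | 0.018 | 4e-9 /base/year × 5e8 bases × 5 years × 1.8e-3 genotyped fraction |

The packaged GBR scenario: five populations W, S, M, O, K with census
12,500 (K: 2,500) and offsets +1.6, 0, +1.6, 0, −1.8 °C. Pairwise
immigration fractions all sit at 0.005 — the midpoint of the genomically
estimated 0.1–1% range; the per-pair point estimates live in supplementary
material not bundled here, so every entry is a documented placeholder, and
the matrix is ordinary config data that users should replace with their own
estimates.

## Neutral AFS module

Unlinked neutral biallelic loci are simulated as independent allele-frequency
trajectories (per-generation Binomial(2N(t), p) resampling) — exact for
unlinked neutral loci and ~1000× faster than individual-based simulation; the
individual-based engine serves as the small-N cross-check oracle in the
tests, not the implementation. Mutation: a monomorphic-ancestral locus gains
one derived copy with probability 2N(t)·μ per generation; polymorphic loci do
not re-mutate (infinite-sites-like approximation appropriate for short tag
SNPs). Loci are initialized at the neutral stationary spectrum
(P(count = k) ∝ θ/k) rather than burning in forward from monomorphism, which
would take ~4N ≈ 120,000 generations at N = 30,000; the tests verify that
forward simulation from monomorphism converges to the same θ/k shape at small
N. θ per locus defaults to 0.05, chosen so roughly a third of tags segregate
in a sample of 84 diploids — typical 2bRAD SNP density; it is exposed in
`NeutralSimSpec`. The decline experiment ("ten populations" = ten independent
replicates, a CLI parameter) samples 84 diploids = 168 chromosomes without
replacement (hypergeometric) and writes unfolded spectra with fixed classes
masked in the AFS text dialect. Demographic-history reconstruction from those
spectra is the job of external inference tools and is out of scope; the
module validates the upstream signal directly — a ten-fold crash depletes the
singleton fraction relative to constant-size controls.

## Numerical and design choices

* **Randomness.** One `numpy` Generator per run, seeded from the scenario
  seed through a SeedSequence (environment and engine get separate child
  streams). The per-generation order of operations is fixed (populations in
  config order; phenotype noise first, then per-destination parentage),
  so runs are bit-reproducible. `esd = 0` consumes no noise draws.
* **Parent sampling** uses inverse-CDF search on the cumulative fitness
  vector — O(c log N) per brood, no per-draw normalization.
* **Mutation sparsity.** Mutation masks are drawn per gamete-locus; normal
  increments are generated only for the hits, so the common case
  (μ ≈ 1e-5) costs almost nothing.
* **Ties and degenerate inputs.** A population whose individuals all have
  zero fitness (possible by floating-point underflow at extreme mismatch) is
  treated as extinct; `choose_parents` raises an explicit extinction signal.
  Census sizes are floored at 2 during burn-in stages (rounding 250/100 up to
  the viability floor) and extinction is < 2 individuals.
* **Variance bookkeeping** uses population-style (ddof = 0) variances so the
  pooled metapopulation variance decomposes exactly into mean
  within-population variance plus size-weighted between-population variance
  of means; this identity is asserted every generation in the tests.
* **Anomaly-sensitivity diagnostic** detrends a mean-fitness trace with
  lowess (span 0.2 of the analyzed window by default — the right order to
  remove the warming trend while keeping generation-scale fluctuations) and
  pairs residuals with sign-inverted anomalies; sensitivity is summarized as
  a rolling residual SD.
* **Equilibrium-stability check.** The claim that total metapopulation
  genetic variation is stationary over the 500 generations preceding warming
  is tested as a relative-drift bound (|fitted linear slope| × 500 < 15% of
  the mean level). A rank-based trend test (Mann-Kendall) is the textbook
  choice but assumes serial independence; the pooled-SD series is strongly
  autocorrelated (genetic drift), and MK rejects a healthy equilibrium run
  spuriously — we observed p < 0.01 in ~4/10 stationary runs even after
  thinning — so the drift bound is the honest test of "stays constant".

## Reduced-scale test conditions

The test suite and the acceptance script run the GBR scenario at 1/10
population sizes with 10× mutation rate (N·μ preserved) and a staged burn-in
of 1,000 + 1,000 + 2,000 generations; the smaller stage populations
equilibrate proportionally faster, so this reaches the same
mutation-drift-migration-selection balance as the full-size plan. Ensemble
checks use ten replicate seeds. Full-size runs remain available through the
packaged scenario unchanged.

## What the synthetic conditions do and do not show

The generator emulates: divergent local thermal adaptation maintained against
0.1–1% per-generation migration; standing-variation-fueled persistence under
gradual warming with warm-adapted populations collapsing first; growing
sensitivity of mean fitness to thermal anomalies as warming progresses; and
the mutation-rate dependence of sustained adaptation. It does not emulate:
linked selection or any genetic map; overlapping generations, age structure
or explicit larval dynamics; density dependence, Allee effects or
reef-state feedbacks; autocorrelated (truly periodic ENSO) anomalies;
symbiont-mediated plasticity (only crudely absorbed into σ and Esd); or
recolonization of extinct habitat. Passing tests therefore speak to the
population-genetic core — selection, drift, migration, mutation and
fitness-linked demography — not to ecological realism of coral reefs.

## Known limitations

* Dominance ≠ 0.5 uses a defensible but non-unique convention (experimental).
* Census sizes are treated as effective sizes; in highly fecund marine
  species the two can differ by orders of magnitude, biasing persistence
  estimates downward.
* The per-pair migration placeholders (all 0.005) flatten real asymmetries
  (e.g. prevailing southward transport); users with directional estimates
  should supply their own matrix.
* Survival times reported by the reduced-scale scenario are not calibrated to
  the full-size system: rescaling preserves equilibrium variation (N·μ) but
  not the absolute efficacy of selection relative to drift (Ns), so
  scaled-down persistence is a qualitative, not quantitative, stand-in.
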