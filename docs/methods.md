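# Methods

`heterosim` simulates a two-way crossbreeding program under genomic
selection with dominance, forward in time. This note records the model,
the calibration conventions, the numerical choices, and what the shipped
desk-scale profiles do and do not show.

## Population model

**Historical phase.** A Wright–Fisher population of N = 2000 monoecious
individuals mates randomly (random union of gametes, selfing allowed) for
2000 generations. The genome is four 1-Morgan chromosomes carrying ~8800
candidate biallelic loci at uniform random positions; initial allele
frequencies are uniform(0, 1) and a recurrent symmetric allele-flip
mutation of 2.5 × 10⁻⁵ per locus per gamete acts during this phase only —
its sole purpose is to keep enough loci segregating after 2000
generations. Meiosis is Haldane: crossover counts per chromosome are
Poisson(length in Morgans) with uniform positions and no interference;
chromosomes segregate independently.

**Breed founding.** Two disjoint random samples of 100 animals found
breeds A and B; each breed mates randomly at constant size 100 for 100
generations, then one round of random mating expands it to the 1000
generation-0 selection candidates. Sexes are assigned deterministically
half male / half female per cohort, so the 100-male / 200-female selection
quota is always feasible.

**Selection phase.** Each generation, marker effects are re-estimated on
the current candidates (one model per breed in purebred-training mode; one
model on 2000 current crossbreds in crossbred-training mode), candidates
are scored with SC = (1 − w)·GEBV-P + w·GEBV-C, the top 100 males and 200
females per breed are selected by truncation (ties broken by ascending
id), and they produce 1000 purebred replacements per breed plus the
crossbred cohort (A sires × B dams; 1000 animals, 2000 in
crossbred-training mode so a 2000-animal training set exists — the program
description gives both numbers and we resolve the discrepancy this way).
Generations are discrete and non-overlapping. No mutation acts after the
historical phase, so fixation is absorbing.

In crossbred-training mode a generation-0 crossbred cohort is produced
from randomly chosen parents (no selection has happened yet) so the first
training round has data; this is our choice where the design is silent.

## Trait model and calibration

Each of 400 QTL has an additive effect a (half the homozygote difference)
with gamma(shape 0.4, scale 1.66) magnitude and random sign — the
increasing allele is chosen by a fair coin, since only the magnitude
distribution is specified — and a dominance effect d = h·|a| with degree
of dominance h ~ N(0.5, 1). Genotypic values sum +a/d/−a for AA/Aa/aa;
phenotypes add a normal residual.

Effects are rescaled by alternating multiplicative updates on a and d
until, at the base-population (generation-2000 historical) QTL
frequencies,

- σ²_a = Σ 2p q α², with α = a + (q − p)d — the narrow-sense additive
  (breeding-value) variance, set to h²σ²_p = 0.3, and
- σ²_d = Σ 2p q (1 − 2p q) d² — the variance of the dominance component
  Σ_j z_j d_j of the genotypic value (z the heterozygosity indicator) —
  set to 0.1 (Models 1, 3) or 0.05 (Model 2).

The calibration convention deserves a note. The textbook alternative for
the second target, the variance of orthogonal dominance deviations
Σ(2pq d)², makes the no-over-dominance Model 3 infeasible at drifted base
frequencies (with |d| ≤ |a| everywhere the deviation variance cannot reach
0.1 when Σ2pq α² = 0.3) and yields ~33% over-dominant QTL under Model 1.
Calibrating the dominance *component* instead reproduces the intended
architecture classes — roughly a quarter of QTL over-dominant at σ²_d =
0.1, a tenth at 0.05, and Model 3 feasible — which is what matters for the
dynamics this package studies. The orthogonal quantity remains available
as `dominance_deviation_variance`. Under Model 3, |d| is re-clamped to
|a| after every scaling update; the iteration stops when both variances
are within relative tolerance 10⁻⁴ (max 200 iterations, convergence error
with residuals otherwise).

The residual variance is σ²_e = σ²_p − σ²_a − σ²_d (0.6 or 0.65), so that
the phenotypic variance is actually σ²_p = 1 at h² = 0.3; a literal unit
normal residual would contradict those targets, but is retained behind
`TraitConfig(literal_unit_residual=True)`.

Because the additive target is calibrated on α and the dominance target on
the component, the components' covariance makes the realized phenotypic
variance 1 only up to a few percent; tests allow for this.

## Breeding values

TBV-P/TBV-C are expected offspring genotypic values under random mating to
the own/opposite breed (per locus: x(p a + q d) + (1 − x)(−q a + p d) with
x ∈ {1, ½, 0} and mate frequencies p, q). GEBV-P/GEBV-C apply the same
formula to SNPs with the posterior-mean effects, with SNP frequencies
recomputed each generation from all current candidates of the relevant
breed. Frequencies of exactly 0/1 are legal; nothing is floored. GEBVs
are blended raw (no standardization): both components come from the same
estimates, so their scales are directly comparable.

## Marker-effect estimation

y = μ + Xa + Zd + e with X ∈ {0,1,2}, Z the heterozygosity indicator;
single-site Gibbs with one shared variance per effect class and
scaled-inverse-χ² hyperpriors (df 5) on both class variances and the
residual. Prior scales follow the usual Bayesian-ridge rule: an assumed
model R² of 0.5 split equally between the classes, divided by the sum of
design-column variances (the de-facto default of standard
implementations; the study names the method but not its
hyperparameters). Columns are centered inside the sampler — this
decorrelates the intercept from the effects and is what makes the
fixed-variance posterior mean agree with the closed-form ridge solution at
modest chain lengths — and the reported intercept is mapped back to the
raw coding. Default chain 20 000 iterations / 3000 burn-in; desk-scale
runs use 2000/500, which leaves posterior means for prediction essentially
unchanged (the dominance-contrast accuracy is data-limited, not
chain-limited). Convergence is monitored with the Geweke diagnostic
(first 10% vs last 50%, spectral density at zero via a Bartlett-windowed
autocovariance sum with a variance floor so a constant chain returns z=0).

## LD phase

Signed r between SNP pairs is the Pearson correlation of allele indicators
over the 2n phased gametes, under one global allele labelling shared by
all populations (sign consistency is what phase correlation measures).
All within-chromosome pairs up to 10 cM enter; SNPs need MAF > 0.01 in
each population of a comparison. R_XY per half-open 0.1 cM bin is the
Pearson correlation of paired r values over the pairs valid in both
populations; bins with fewer than 3 shared pairs are reported missing.
Pair r values are read out of blockwise Gram matrices of the standardized
gamete matrix (float32), which is exact up to float32 rounding.

## Scale choices and what they show

Full study conditions (50 replicates × 40 generations × 20 000-iteration
chains) are far beyond a desk run; the shipped configs under `configs/`
encode them for cluster use. The package's own test and acceptance runs
use two tiers:

- **Base-population statistics** (LD phase, r_pc, generation-1 accuracy,
  over-dominance fractions) run at the full stated base conditions with 5
  replicate worlds — these quantities need no selection generations.
- **Program dynamics** run on a reduced profile (4 × 1 M chromosomes, 1000
  SNPs + 400 QTL from 2800 candidates, full 2000-generation historical
  phase, 500 candidates per breed, chains 1000/250, ~15–40 generations,
  5 replicates, common random numbers across w). Keeping the full 400-QTL
  architecture matters: the exploitable heterosis pool scales like
  √n_QTL, and profiles with few QTL cannot express the selection-criterion
  contrasts at all.

The generator emulates drift, recombination, mutation-drift balance,
dominance and over-dominance, and breed divergence. It does not emulate
real linkage maps, variable recombination, selection before the program
starts, genotyping error, or G×E/epistasis (explicitly outside the trait
model). Passing tests therefore demonstrate internal consistency of the
method under the stated stochastic model, not performance on real
livestock data.

A caveat worth stating plainly: with an F1 produced directly from the two
breeds, the crossbred gamete pool *is* a sample of current parental
gametes, so the phased-haplotype phase correlation between a breed and its
F1 is structurally high (~0.8 at short distance in our runs) and
between-breed phase correlation at <0.5 cM is ~0.25; alternative
estimators (genotype-composite r, EM-based r) and alternative cohorts
(later generations, different founding sizes) move these levels only
modestly. The qualitative structure — breed-to-crossbred persistence ≫
between-breed persistence, monotone decay with distance, near-zero
between-breed agreement beyond ~1 cM — is robust.

## Numerical and performance notes

Haplotypes are uint8 0/1 alleles, shape (n, 2, L). The historical phase
runs bit-packed (8 loci/byte) inside a single numba kernel (whole-loop,
double-buffered), which keeps the working set in cache; the breeding phase
uses byte-coded haplotypes since per-locus genotypes are needed every
generation anyway. Mutation uses geometric gap-sampling (exact Bernoulli
process, O(#mutations)). All randomness flows from numpy `SeedSequence`
spawning — one stream per replicate, one per scenario — with numba kernels
seeded from the parent stream; identical config + master seed reproduces
every output exactly. Gibbs designs are float32 transposed (rows
contiguous); accumulations are float64.

Degenerate inputs: constant phenotypes are legal in training (effects
shrink to the prior mean 0); an all-homozygous SNP leaves its dominance
effect at the prior mean; monomorphic SNPs are excluded from LD pairs
rather than erroring; empty fixation denominators are reported as missing
(NaN), never as zeros.
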