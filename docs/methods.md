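# Methods

This package implements the two competing quantitative-genetic analyses of
plumage-colour inheritance in the common buzzard (*Buteo buteo*): an exact
Mendelian segregation analysis of a three-morph classification, and a
Bayesian pedigree ("animal") model of the seven-point colour score. Because
the underlying field pedigree is not publicly deposited, the package also
ships a synthetic-data generator that emulates the structure of the study
population, and every claim the test suite makes is a claim about method
behaviour on such data.

## Pedigree machinery

A pedigree is validated as a directed acyclic parent→offspring structure:
unique non-empty ids, resolvable parent references, no individual in both
parental roles, sexes consistent with roles (unknown sex permitted), and a
topological order with parents first. Unknown-parent codes `0`, empty and
`NA` are accepted on input; `0` is written on output (PLINK `.fam`
convention). Input row order never matters.

Link statistics count mother–offspring and father–offspring links and
unordered sibling pairs; a pair sharing both parents is a full-sib pair
only, one sharing exactly one parent a half-sib pair.

The additive relationship matrix A is built by the tabular recurrence
(A(i,j) = ½(A(s,j)+A(d,j)), A(i,i) = 1 + ½A(s,d)) over the topological
order, and its sparse inverse directly from pedigree structure by
Henderson's rules with inbreeding-corrected Mendelian-sampling variances
d_i = 1 − ¼(A(s,s)+A(d,d)) (¾ and 1 for one and zero known parents). The
d_i are taken from the dense tabular diagonal rather than the
Meeuwissen–Luo algorithm; pedigrees in this problem are a few thousand
individuals at most, where the dense pass is cheap and simpler. Tests
verify A against an independent Wright path-counting implementation
(including inbred cases) and A·A⁻¹ = I to 1e−8.

## Mendelian segregation analysis

The seven-point score (1 = very dark … 7 = very light) is lumped to
dark/intermediate/light. Four alternative lumping scenarios are shipped as
configurable mapping tables constrained to be total, monotone and
extreme-preserving; scenario 1 ({1,2}→D, {3,4,5}→I, {6,7}→L) is the
default. The published scenario boundaries beyond scenario 1 are not
printed in the sources available to us, so scenarios 2–4 are plausible
placeholders meant to be overridden — every analysis accepts a scheme
argument.

Under the one-locus two-allele hypothesis D and L are opposite homozygotes
and I the heterozygote; expected offspring distributions per unordered
parental combination follow from gamete enumeration in exact rational
arithmetic (triples sum to 100 exactly).

Observed crosses are tabulated for offspring whose own score and both
parents' scores are known; others are skipped and counted. The published
Friesland cross table is reconstructed from printed percentages and totals
via `round(pct·N/100)`; reconstruction is verified to reproduce the printed
percentage within 0.05 (the printed table rounds half-cases like 18.75
inconsistently, so exact 1-decimal equality is slightly too strict) and to
sum to the printed N.

Goodness of fit uses the exact multinomial test: p is the total probability
of outcomes no more probable than the one observed, ties included; an
observed count in a zero-probability class yields p = 0 exactly (the
hypothesis is refuted outright rather than the class being dropped). A
seeded Monte Carlo variant with the add-one correction and an asymptotic
Pearson option are provided; the method used is recorded in the result.
Cross-cross comparisons (e.g. intermediate proportion in I×I vs D×L) are
two-sided 2×2 tests, Pearson chi-square without continuity correction by
default or the exact conditional (Fisher) test.

Count tests treat offspring as independent although siblings share a nest
and parents. The family bootstrap resamples whole families with replacement
within each parental combination and takes
p = min(1, 2·min(#{d*≤0}, #{d*≥0})/B) for the difference in focal-morph
proportions; no add-one correction is applied, so complete separation gives
p = 0. Simulation tests confirm it matches the chi-square test without
family heterogeneity and is more conservative under strong clustering.

## The animal model

The seven-point score is treated as a Gaussian response — the analysis this
package reproduces models the ordinal score linearly, and an
ordinal-threshold response is out of scope. Model 1 partitions phenotypic
variance into additive-genetic (V_A, covariance V_A·A), maternal-identity
(V_M), paternal-identity (V_F) and residual (V_R) components; model 2 adds
nest-of-rearing (V_N) and birth-year (V_Y). The intercept is always
present; offspring sex can be screened as a fixed effect and is dropped
when its 95% credible interval covers zero. Records are the scored
individuals; all pedigree members span the animal-effect dimension. Records
with an unknown mother/father/nest/year receive their own singleton level —
information-neutral under the exchangeable prior — rather than being
dropped.

Estimation is a systematic-scan Gibbs sampler. Location effects are updated
jointly per random-effect block from their Gaussian full conditionals:
identity-structured blocks factor into independent level-wise normals,
while the animal block is drawn exactly by a perturbation scheme — sample
u0 ~ N(0, V_A·A) through the pedigree recursion (generation-vectorised,
using the Mendelian-sampling variances d_i), perturb the data with
N(0, V_R) noise, and solve the sparse system C = Z'Z/V_R + A⁻¹/V_A with a
sparse LU factorisation, giving a draw from N(C⁻¹Z'y*/V_R, C⁻¹). Each
variance is then drawn from its scaled-inverse-gamma full conditional with
shape (ν+q)/2 and scale (νV + u'K⁻¹u)/2 (K = A for the animal term,
identity otherwise; residual analogous with q = number of records). The
(ν, V) prior notation maps to inverse-gamma shape ν/2, scale νV/2; the
sampling identity scale/Gamma(shape) is unit-tested against the
inverse-gamma density. Identical seed and configuration give bit-identical
chains. Non-finite draws abort with the iteration index; a zero-variance
response is rejected.

Summaries are posterior means with central 2.5–97.5% quantile credible
intervals (quantile, not HPD, recorded in the output metadata), per-draw
ratios V_x/V_P (which sum to one by construction — asserted on every
retained draw), h² = V_A/V_P, the maternal–paternal contrast
(V_M − V_F)/V_P, and the lag-1 autocorrelation of each thinned chain with a
flag at ≥ 0.05.

### Chain lengths and mixing

The production default is 1 000 000 iterations, 100 000 burn-in, thinning
10 (reading the source analysis's "1 000 000 samples" as total iterations;
retained-draw readings are reachable by configuration). Mixing of the
V_A–V_R trade-off is slow in a two-generation pedigree where every
individual is scored: at study scale the thinned (10) h² chain has lag-1
autocorrelation ≈ 0.85, and 100 000-iteration chains reproduce the
posterior-mean h² to about ±0.01 across seeds. The package's "desk-scale"
configuration is therefore 60 000/12 000/10 (~2–3 minutes per fit);
shorter chains are used in tests only where the tolerance is much wider
than the Monte Carlo error. The maternal/paternal components are nearly
aliased with family structure and mix slowest; inference about
(V_M − V_F)/V_P needs the longer chains.

### Priors

The default prior on every variance is inverse-gamma with ν = 0.002, V = 1.
Sensitivity checks show h² is insensitive across genuinely weak settings
(ν ∈ {0.002, 0.02} changes the posterior mean by far less than 0.05 at
study scale). A unit-scale prior (ν = 1, V = 1) is *not* weak here: its
density factor exp(−νV/2x) suppresses values of x much smaller than V, so
the small parental components (truth ≈ 0.1–0.13) are pulled upward and h²
down by ≈ 0.1. This is a property of the prior family, not of the sampler,
and is why the package keeps ν = 0.002 as the default.

### Validation

The sampler is validated three independent ways: (i) on data generated
exactly from the model (animal + residual, study pedigree) the posterior
covers the truth with no drift between 10k and 40k iterations; (ii) on
balanced paternal half-sib designs the posterior mean of the sire variance
matches the closed-form ANOVA (expected-mean-squares) estimator within
combined Monte Carlo error; (iii) a parameter-recovery grid over true
h² ∈ {0.2, 0.5, 0.8} (~21 replicates at reduced scale) keeps absolute bias
≤ 0.1 and pooled 95%-CrI coverage ≥ 85%.

## Synthetic data

The generator emulates the study population's structure. Breeding pairs
(default 202) are formed by matching sire and dam "pair slots": most
parents hold one pair; with probability 0.12 a parent is a serial breeder
holding 2 + Poisson(2.5) pairs, reproducing the long right tail of
per-parent offspring totals that a multi-year territory system produces.
Family sizes are zero-truncated negative binomial (mean 5.2, dispersion
1.4, calibrated so ~989 offspring remain after capping parent totals at the
observed maximum of 31), split into broods of ≤ 4 chicks in consecutive
years, one nest per pair-year. Defaults yield ~960–1050 offspring from
~280–300 parents, father means ~6.5–7 (median ~5, max 31) and full-sib pair
counts near the study's; half-sib pair counts reach roughly half the
study's figure — matching those exactly would require distorting the
printed family-size and per-parent ranges, so the shortfall is accepted and
the heritability analysis is correspondingly slightly less informed than
the real data.

Mendelian phenotypes: founder genotypes are Hardy–Weinberg at a
configurable dark-allele frequency (default 0.5), offspring draw one allele
per parent, genotype fixes the three-morph class, the seven-point score is
uniform within the class band ({1,2}/{3,4,5}/{6,7}, mirroring lumping
scenario 1 so the mapping inverts the simulation exactly), and an optional
misclassification rate moves scores one point.

Polygenic phenotypes: breeding values follow the pedigree recursion
(founders N(0, V_A), offspring midparent + Mendelian-sampling deviate);
maternal/paternal/nest/year effects are iid normal. Individuals whose
mother (etc.) is unrecorded still receive their own independent effect draw
— the effect exists, it is merely unshared. Without this the founders'
phenotypic variance is too small and heritability recovery is biased
upward by ~0.08. Liability is the sum plus residual and is retained
alongside the score. Default variances are the study-scale partition
V_A = 1.84, V_M = 0.13, V_F = 0.11, V_R = 0.16 (V_P = 2.24, h² ≈ 0.82).
The six thresholds cut the liability at the normal quantiles of cumulative
(4, 15, 35, 65, 85, 96)% of total variance, giving a unimodal, centred
seven-class distribution; they are configurable. Discretising the liability
onto seven classes attenuates the observed-scale h² slightly (posterior
means ≈ 0.78–0.87 across seeds against a liability-scale truth of 0.82).

What the simulations do not emulate: extra-pair paternity (assumed absent),
assortative mating, overlapping generations (no offspring becomes a
parent), observer drift in scoring, and the exact distribution of parental
morph combinations (pair morphs arise from the founder genotype/liability
distributions rather than being forced to the published offspring totals).
Passing tests therefore demonstrate correct method behaviour under these
idealised conditions, not properties of the real population.

## Numerical choices

- Exact multinomial ties count as "as extreme" with a 1e−12 relative
  tolerance on pmf comparisons.
- Goodness-of-fit statistic is Pearson X² over positive-expectation cells,
  infinite when an impossible class is observed.
- The sparse system in the animal block is refactorised each iteration
  (structure fixed, only two scalars change); with the two-generation
  sparsity this costs ~1.5 ms per iteration at study scale.
- Degenerate 2×2 margins return p = 1 with a warning rather than an error.
- Missing-value singleton levels are deterministic functions of the record
  id, so runs are reproducible.
- The fixed-effect sex coding is M = +0.5, F = −0.5, unknown = 0.

## Known limitations

- No ordinal-threshold (liability-scale) response model; heritability is on
  the observed score scale, as in the analysis being reproduced.
- No REML/ML alternative, dominance, X-linkage or genomic relationships.
- Lumping scenarios 2–4 are placeholders pending published definitions.
- The half-sib link count of the default synthetic population underruns the
  real study (see above).
- The family bootstrap requires ≥ 2 families per combination and reports
  granular p-values at small B.
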