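# buteo

Inheritance analysis of plumage colour polymorphism in the common buzzard
(*Buteo buteo*), for quantitative geneticists and behavioural ecologists
working with colour-scored field pedigrees.

Buzzard plumage varies continuously from very dark to very light and is
traditionally lumped into three morphs — dark (D), intermediate (I) and
light (L). A classic hypothesis holds that the morphs segregate at one
locus with two alleles, D and L being the homozygotes and I the
heterozygote, with heterozygote advantage maintaining the polymorphism.
This package implements the two analyses that confront that hypothesis
with a two-generation pedigree of colour-scored birds:

1. **Mendelian segregation analysis.** For each unordered parental morph
   combination, the one-locus model predicts offspring proportions by
   gamete enumeration (e.g. I×I → 25/50/25, D×L → 0/100/0). The package
   tabulates observed crosses, computes exact multinomial goodness-of-fit
   p-values, compares combinations with exact or chi-square 2×2 tests, and
   offers a family-level bootstrap that respects the non-independence of
   nest-mates.

2. **Bayesian animal model.** Treating the seven-point score as a Gaussian
   trait, a Gibbs-sampled linear mixed model partitions phenotypic
   variance V_P into additive genetic variance V_A — structured by the
   pedigree relationship matrix A — plus maternal-identity, paternal-
   identity, optional nest and birth-year, and residual components:

       y = Xβ + Z_a u_a + Z_m u_m + Z_f u_f [+ Z_n u_n + Z_y u_y] + e,
       u_a ~ N(0, V_A·A),  u_x ~ N(0, V_x·I),  e ~ N(0, V_R·I)

   with inverse-gamma (ν = 0.002, V = 1) priors on all variances.
   Heritability is h² = V_A/V_P; posterior means, 95% credible intervals,
   per-draw variance ratios and the maternal–paternal contrast
   (V_M − V_F)/V_P are reported with lag-1 autocorrelation diagnostics.

Because the field pedigree behind the published analysis is not deposited,
the package includes a synthetic-data generator that emulates the study
population (≈202 breeding pairs, ≈990 scored offspring, long-tailed
per-parent offspring totals up to 31) under either inheritance model, so
the full pipeline is testable end to end. See `docs/methods.md` for the
model details and design choices.

## Worked example

```python
import buteo as bt

# study-emulating pedigree with polygenic phenotypes (h2 = 0.82 truth)
ped = bt.simulate_pedigree(bt.PedigreeSimConfig(seed=1))
data = bt.simulate_polygenic(ped, bt.PolygenicSimConfig(seed=2))
print(len(data), bt.link_counts(data))
# 1231  LinkCounts(mother_offspring=938, father_offspring=938,
#                  full_sib=2964, half_sib=4822)

# segregation analysis under lumping scenario 1
ct = bt.tabulate_crosses(data, bt.SCENARIOS["1"])
print(ct.percentages().round(1).loc[["IxI", "DxL"]])
#          n_D   n_I   n_L
# IxI     11.7  74.2  14.0
# DxL      5.9  78.4  15.7
```

I×I pairs produce 74% intermediates where the one-locus model predicts
50%, and D×L pairs only 78% where it predicts 100% — polygenic inheritance
reproduces exactly the deviation pattern reported for the real population.
The published counts themselves give

```python
res = bt.compare_crosses(bt.study_cross_table(), "IxI", "DxL", "I")
# chi2 = 12.60, p = 0.00039   (opposite direction to the Mendelian prediction)
```

Fitting the animal model to the simulated data (desk-scale chain,
60 000 iterations, ~2 min):

```python
chain = bt.fit_animal_model(data, bt.ModelSpec.model1(), bt.MCMCConfig.desk_scale(seed=3))
print(bt.summarize(chain).loc[["h2", "V_M/V_P", "V_F/V_P", "V_R/V_P"]])
#            mean  ci_low  ci_high
# h2        0.749   0.627    0.862
# V_M/V_P   0.100   0.031    0.165
# V_F/V_P   0.025   0.001    0.091
# V_R/V_P   0.125   0.003    0.259
```

The 95% credible interval comfortably covers the simulated truth
(h² = 0.82); production analyses should use the full-length default chain
(1 000 000 iterations, burn-in 100 000, thinning 10).

A command-line interface wraps the same functionality:

```sh
buteo simulate --mode polygenic --pairs 202 --seed 1 --out ped.csv
buteo pedstats ped.csv
buteo segtest ped.csv --scenario 1 --method exact --out segregation.tsv
buteo animal ped.csv --model 1 --seed 3 --out posterior.tsv
buteo all ped.csv --seed 1 --out results/   # everything + run manifest
```

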