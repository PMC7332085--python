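# polityscale

Scaling analysis of human sociopolitical complexity across ethnolinguistic
populations.

Cross-cultural databases code each society's **jurisdictional hierarchy**
ω ∈ {1..5} — from politically acephalous communities (ω = 1) to multi-tiered
states (ω = 5) — alongside its population size *N*, geographic range *A*
(km²), and hence population density *D* = *N*/*A*. Treating ω as a
Horton-Strahler order, this package asks whether societies are
*statistically self-similar* across the hierarchy, and how the allometry of
range on size is reconfigured level by level. It is aimed at quantitative
anthropologists and human-ecology researchers working with society-level
tabular data.

## What it computes

**Branching ratios and Horton laws.** With N̄_ω = exp(mean ln N at level ω)
the geometric mean, the branching ratio is R_N = N̄_{ω+1}/N̄_ω (and R_A for
range). Constant ratios are equivalent to exponential growth across levels,

    N̄_{ω+k} = N̄_ω e^{λk},   Ā_{ω+k} = Ā_ω e^{γk},   λ = ln R_N, γ = ln R_A,

estimated by OLS of the level mean-logs on ω. Density then grows at
θ = λ − γ per level — an exact identity here, because D is always derived
per record. Self-similarity of the *means* implies the allometric
prediction Ā ∝ N̄^β with β = γ/λ.

**Generalized Horton laws.** Self-similarity of the *entire distributions*
is checked by rescaling each level's values by its mean and testing whether
the complementary CDFs collapse onto one curve (max pairwise two-sample KS
distance, permutation null).

**Spatial mixed scaling model.** Within levels, the allometry
A = A₀,ω N^{β_ω} is fitted on the log scale as ln A ~ ln N × factor(ω) with
nested random intercepts for continent / language family / language, a
Matérn spatial field over great-circle distance, and ML estimation; the
cross-level trends of ln A₀,ω and β_ω quantify how density is reconfigured
as complexity grows. Goodness of fit is assessed by stratified 70/30
out-of-sample validation.

**Synthetic data.** `polityscale.synth` generates society tables whose
per-level composition, lognormal moments, level-specific allometry, nested
grouping, and spatial autocorrelation match the published study conditions
(n = 412/351/187/140/30 per level), so every stage is testable without any
proprietary data.

## Worked example

```bash
python analysis/01_generate_data.py --seed 0
python analysis/02_branching_ratios.py
python analysis/03_distribution_collapse.py
python analysis/04_spatial_model.py
python analysis/05_cross_validation.py
```

The first script writes `results/societies.csv` (1,120 synthetic societies).
The second prints, for this seed:

```
  population size: rate +1.810  branching ratio 6.11 (5.06-7.39)  R2 0.997  self-similar: True
 geographic range: rate +1.122  branching ratio 3.07 (2.34-4.03)  R2 0.983  self-similar: True
          density: rate +0.688  branching ratio 1.99 (1.60-2.47)  R2 0.972  self-similar: True
predicted exponent beta = gamma/lam = 0.620 (se 0.051): range grows as N^0.62 across levels
```

Each level of hierarchy multiplies the typical population ~6-fold and the
typical range ~3-fold in this replicate (a high draw; the configured rates
are exp(1.48) ≈ 4.4 and exp(0.64) ≈ 1.9), so density roughly doubles per
level, and the mean-log points are linear in ω (R² ≥ 0.97, all means inside
the 95% band). The spatial model step prints the fixed-effect table, the
per-level parameters, and their trends:

```
intercepts change by factor 0.48 per level (slope -0.744): area per capita falls with complexity
elasticities change by factor 1.062 per level (slope +0.0598): spatial packing steepens with complexity
train: n = 784, R2 (corr^2) = 0.911,  test: n = 336, R2 (corr^2) = 0.826
```

The same stages are available on any CSV/TSV/GeoJSON society table through
the `polityscale` command (`generate`, `summaries`, `branching`, `collapse`,
`mixedfit`, `crossval`, `all`) or the library API (`run_full_analysis`).

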