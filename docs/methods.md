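# Methods

This note documents the models, estimators and design choices behind
`lepmon`, a pipeline for long-term light-trap monitoring of tropical moths:
what each stage assumes, which knobs matter, and what the synthetic data
generator does and does not emulate.

## The monitoring design

The package is organised around a fixed survey design: `I` trap sites
sampled four times a year (one dry-season survey, around March, and three
wet-season surveys, around May, September and November) over `J` years.
Counts are per site, survey and species. Calendar dates are mapped to a
survey index 1–4 by nearest anchor month (circular in months, ties to the
earliest anchor); the anchor months are configurable because real
programmes drift around their nominal schedule. Site-years in which no
survey ran are represented as missing, never imputed at ingest.

## Trend models (TRIM family)

Annual counts `f_ij` (site `i`, year `j`, summed over the four surveys) are
modelled with log-linear Poisson regressions in three nested forms:

1. *no time effects* — `ln μ_ij = α_i`
2. *linear trend* — `ln μ_ij = α_i + β (j − 1)`
3. *time effects* — `ln μ_ij = α_i + γ_j`, `γ_1 = 0`

fitted by maximum likelihood (IRLS) over observed cells only. Assumptions:
counts are conditionally Poisson given site and year effects; all sites
share the same temporal pattern (no site × year interaction); missing
cells are missing at random so their fitted values can be read off the
model. Sites with no positive counts cannot support a log-scale intercept
and are dropped with a warning.

Numerical choices:

- **Overdispersion** `σ² = X²/df` (Pearson), floored at 1, multiplies the
  parameter covariance. The floor means standard errors are never shrunk
  below their Poisson values; with truly Poisson data coverage of the 95%
  slope interval is therefore slightly above nominal (we measure ~95–97%).
- **AIC convention** is the residual-deviance form `AIC = G² − 2·df`,
  which is negative for well-fitting models. This matches the convention
  used in monitoring reports built on TRIM output; the alternative
  `−2ℓ + 2p` form orders nested models identically.
- **Overall multiplicative slope.** For the linear model, `m = exp(β)`
  with SE by the delta method. For the time-effects model the yearly
  totals factorise as `exp(γ_j) · Σ_i exp(α_i)`, so the least-squares
  slope of log totals on year rank is a fixed linear combination of the
  `γ̂` and its variance follows from their covariance. At `J = 2` both
  models are saturated in time and agree exactly (verified to 1e-8).
- **Trend categories** compare the 95% Wald interval `m ± 1.96·SE` with 1
  and the ±5%-per-year thresholds 0.95/1.05: strong/moderate increase,
  stable, uncertain, moderate/steep decline. The rule partitions the
  whole (m, SE) half-plane; an enumerated grid test asserts this.
- **Model selection** takes the lowest AIC among the candidates and
  separately flags "none of models significant" when every candidate's
  goodness-of-fit p falls below 0.01 and no Wald test on time parameters
  reaches 0.05. The flag threshold is a package choice; monitoring
  reports that use it rarely state their rule. Note that with the
  residual-deviance AIC, spurious time effects enter whenever the deviance
  drop exceeds twice the extra degrees of freedom, which happens for about
  20% of null draws — model 1 is selected on pure site-effect data about
  80% of the time, not more.

Fit quality is reported through Pearson `X²` and deviance `G²` with
chi-square p-values on `df = n_obs − n_params`. The IRLS implementation is
cross-checked in the test suite against an independent GLM fitter on the
same design matrices (agreement to 1e-8).

## Species traits and the functional space

Five variables per species feed the functional classification:

| trait | units | meaning |
|---|---|---|
| FW | mm | forewing length; body size, dispersal ability |
| TW | mm | thorax width; flight-muscle mass |
| WingLoad | — | TW/FW; index of flight strength |
| Var_Peak | [0, 1] | dispersion of the yearly peak survey |
| DBIF | (0, 1] | fraction of host-plant families used |

**Var_Peak** is defined here as a circular variance: for each year with a
non-zero total the peak survey (largest site-summed count, ties to the
earliest survey) is placed on the 4-survey circle at angle
`2π(p − 1)/4`, and Var_Peak = 1 − R where R is the mean resultant length.
0 means the peak falls in the same survey every year (strict seasonality);
1 means peaks uniform around the annual cycle. The index is invariant to
scaling all counts and uses site-summed counts; a per-site variant would
confound seasonality with spatial patchiness at these sample sizes.
All-zero years are excluded; never-seen species are flagged missing.

**DBIF** is distinct host families used over distinct families in the
whole database, so it is non-decreasing in a species' own host list and
non-increasing in database growth; small values mean specialists.

The analysis matrix takes complete rows only, z-standardised per column
(traits are on incommensurable scales), and the **functional space** is
the full eigendecomposition of the resulting correlation structure. All
axes are kept, so Euclidean distances among PCA scores equal distances in
the standardised trait space exactly — clustering in the space is
clustering on the traits (asserted to 1e-9 on merge heights). Axis signs
follow a deterministic convention (largest-magnitude loading positive).

**Functional groups** come from agglomerative clustering with Ward linkage
on the scores. `k` defaults to 5 (the group count used in the motivating
saturniid programme) with an automatic mode maximising mean silhouette
over k ∈ 2..8. Euclidean/Ward is the package's choice: on all-numeric PCA
scores the Gower dissimilarity used by "daisy"-style workflows reduces to
a range-normalised Manhattan distance anyway, and Euclidean distance is
the one the functional space is built to preserve; both the metric and
linkage are arguments for users who want otherwise.

## Phylogenetic clustering of functional groups

For each group with ≥ 2 members the mean pairwise patristic distance (MPD)
is compared against a null built from global tip-label permutations — one
shuffle scores all groups, mirroring relabelling the tips of a drawn tree.
With 999 permutations the two-tailed p doubles the smaller tail with the
+1 correction, `p = 2·min(#{null ≤ obs} + 1, #{null ≥ obs} + 1)/(n+1)`,
capped at 1, so p = 0 is impossible and the test is valid (measured type-I
error 5.3% at α = 0.05 over 1,000 random groups). MPD is presence-only
(no abundance weights) and invariant to tree rotation. Singleton groups
are skipped with a warning. No significance threshold is hard-coded.

## Seasonal forecasting

Survey-level series (4 observations per year) are described with sample
ACF/PACF (white-noise band ±1.96/√n) and forecast eight surveys (two
years) ahead with a seasonal ARIMA of period 4, default orders
(1,0,0)×(1,0,0)₄ with a constant, fitted by maximum likelihood; `auto=True`
searches a small order grid by AIC. An optional harmonic pre-step (one
sine/cosine pair at period 4, default off) handles series dominated by a
fixed annual cycle; it is off by default because the seasonal AR term
already carries a stable cycle, as the noiseless-cosine check shows
(forecast MSE < 0.01% of squared amplitude).

## Climate covariates and abundance regressions

Covariates per survey fall into day-of-survey (same-day temperatures,
rainfall), month-of-survey (rainfall sum, mean soil humidity and solar
radiation) and lagged bands. Lagged windows cover the 15 or 30 days
*strictly before* the survey day — larval development precedes the trap
night — and include accumulated **degree-days**
`Σ max(0, (Tmax + Tmin)/2 − base)` (base 10 °C by default, configurable;
thermal thresholds for Saturniidae are not well established) and mean
minimum temperature. The monthly ENSO index joins by survey month.

Abundance responses are `log(x + 1)` survey totals. Selection is a
collinearity screen first — predictors whose tolerance `1 − R²_j` against
the others falls below 0.001 are removed, worst first (the published
description of this screen inverts the inequality; it is implemented here
the only way that is meaningful) — then bidirectional stepwise AIC from
the intercept model. Reported F and adjusted R² satisfy the exact OLS
identities, which is also how the published trait-slope regression summary
(F(2,8) = 4.66 at n = 11 ⇒ adjusted R² = 42.3%) is checked for internal
consistency.

## Community metrics

- **ICE** follows the Lee–Chao incidence-coverage formulation with the
  standard infrequent-species cutoff of 10 incidences: sample coverage
  `C = 1 − Q₁/N_infr`, bias-corrected `γ²` floored at 0,
  `ICE = S_freq + S_infr/C + (Q₁/C)·γ²`. ICE ≥ observed richness wherever
  defined; the all-uniques case (zero coverage) is declared undefined
  rather than patched.
- **Accumulation curves** randomise sample order (default 100 times);
  the mean curve is monotone and ends at observed richness by construction.
- The **cryptic-species discovery curve** is fitted as a reciprocal
  logarithm `y = 1/(a + b·ln x)` by least squares on the original scale,
  ranked by AICc against Michaelis–Menten and asymptotic-exponential
  alternatives; the parameterisation is a package choice and an argument.
- **Morisita–Horn** similarity for abundance data; scale-invariant and
  symmetric.
- **NMDS** on Bray–Curtis distances uses non-metric MDS started from a
  classical-scaling (PCoA) configuration plus random restarts, keeping the
  lowest Kruskal stress, and rotates the result to principal axes so axis
  1 carries the dominant variation. Axes are sign/rotation indeterminate,
  so axis–covariate association is reported as |Pearson r|. Perfect
  rank recovery of a latent gradient is only expected while the gradient
  is unsaturated (no site pairs at Bray–Curtis ≈ 1); longer gradients
  horseshoe, which is a property of the distance, not the optimiser.
- **CCA** (canonical correspondence analysis) reports the constrained
  fraction of total inertia and a pseudo-F with a global permutation test
  (999 row permutations of the covariate table by default); collinear
  covariates are dropped greedily with a warning.

## The synthetic-data generator

`simulate_counts` draws from exactly the structure the analyses assume:

    ln μ_{s,i,j,t} = a_si + ln(m_s)(j − 1) + κ_s cos(2π(t − φ_s)/4)
                     + e_s·ENSO_j + anomaly_j

with Poisson or negative-binomial counts (default NB with shape θ = 5 —
light-trap catches are overdispersed: trap nights share weather and moon
conditions that the model does not resolve). The default community spreads
seasonal concentration κ over 0.2–1.6, staggers peak surveys over all four
positions and mixes ENSO sensitivities 0–0.5, so that derived traits vary
across species instead of collapsing; the cosine kernel makes κ map
monotonically onto Var_Peak (κ → ∞ gives Var_Peak → 0). The default
design is 10 sites × 8 years × 4 surveys. Anomaly years take a
multiplicative bump applied to all species, emulating outbreak years.

Trees are Yule (pure birth) rescaled to unit depth; wing traits evolve by
Brownian motion on the log scale (or i.i.d. draws in the no-signal case);
host records draw a Beta-distributed inclusion probability per species to
span specialists to generalists. Climate is a sinusoid-plus-noise daily
series with `Tmax ≥ Tmin` enforced by a strictly positive spread, seasonal
gamma rainfall, and a monthly AR(1) ENSO index (φ = 0.9, marginal sd 0.8).
In `simulate_bundle` the annual-mean ENSO from the climate module drives
the count model, so lagged-climate analyses have genuine signal.

What the generator does **not** emulate — and hence what passing tests do
not establish about field data: species-abundance distributions of real
assemblages (no log-series tail of rarities), trap-level detection
covariates (moonlight, lamp degradation), within-season phenology finer
than the 4-survey cycle, spatial autocorrelation among sites, serial
correlation of counts across years beyond the ENSO term, and any coupling
between traits and population dynamics (trait–trend relationships in the
synthetic data are null unless constructed).

## Validation scale

The validation experiments (`lepmon.validation`, run by
`scripts/acceptance.py` and the acceptance tests) use the study design
itself where it is defined — 200 replicates of 10 sites × 8 years for
slope recovery, 13 published (slope, SE) pairs for the categorisation
example, 1,000 trials / 999 permutations for MPD calibration, 100
replicates of 3 true + 7 noise predictors at n = 32 for stepwise power —
and modest free sizes elsewhere (50 random matrices for the model-family
checks, a 64-tip balanced tree for clade power). The whole battery runs in
well under a minute.

## Known limitations

- TRIM's serial-correlation option and covariates inside the trend models
  are not implemented; indices from sparse matrices lean on the
  missing-at-random assumption.
- The "none of models significant" rule is a package convention.
- Degree-day base temperature is a guess (10 °C) pending taxon-specific
  thresholds.
- The stepwise regressions are explanatory, not predictive; AIC stepwise
  admits ~1–2 spurious predictors per model at these sample sizes (we
  measure a mean of ~1.4 false inclusions alongside 100% true-predictor
  recovery).
- NMDS stress and CCA permutation p-values depend on the random seed;
  both are exposed and default-seeded for reproducibility.
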