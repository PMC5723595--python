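# lepmon

Trend models, functional classification and community metrics for
long-term light-trap monitoring of tropical moths.

Long-term monitoring programmes for tropical insects — the motivating case
is the saturniid moth survey on Barro Colorado Island, with traps at 10
sites run four times a year — need a repeatable analysis chain to turn raw
per-site, per-night species counts into defensible statements about
population trends and their climatic drivers. `lepmon` implements that
chain as a tested Python library with a thin `moth` command line:

- **Ingestion** of delimited count tables with a configurable survey
  calendar; annual site × year matrices with explicit missingness.
- **TRIM-style trend models**: the three nested log-linear Poisson
  site × year models (no time effects / linear trend / free time effects),
  fitted over observed cells with overdispersion-corrected standard
  errors, compared by the TRIM AIC convention `G² − 2·df`, summarised by
  an overall multiplicative yearly slope `m` (m = 1.05 ⇒ +5%/year) with a
  delta-method SE and the standard trend categories (strong/moderate
  increase, stable, uncertain, moderate/steep decline) from the 95%
  interval against the 0.95/1.05 thresholds.
- **Species traits and functional groups**: wing load (thorax width /
  forewing length), a circular-variance seasonality index (Var_Peak), a
  diet-breadth index (DBIF); PCA functional space on the standardised
  trait matrix and Ward clustering into functional groups.
- **Phylogenetic structure**: mean pairwise patristic distance (MPD) per
  functional group against a tip-label permutation null, two-tailed.
- **Seasonal forecasting**: ACF/PACF diagnostics and two-year-ahead
  forecasts with a seasonal ARIMA of period 4.
- **Climate drivers**: survey-level covariates including lagged
  degree-day accumulation, and stepwise (AIC) multiple regressions of
  log(x+1) abundance after a collinearity screen.
- **Community metrics**: ICE richness estimation, randomized species
  accumulation, reciprocal-logarithm discovery curves, Morisita–Horn
  similarity, NMDS on Bray–Curtis distances, and CCA with a permutation
  test.
- **Synthetic data**: a generator producing counts, traits, trees, host
  records and climate series with exactly the structure the analyses
  assume, so the whole pipeline is exercisable without any field data.

See `docs/methods.md` for the models, their assumptions and the numerical
choices.

## Worked example

Simulate a 10-site × 8-year monitoring bundle whose species increase 10%
a year, then fit the trend-model family to one species and categorise it:

```python
import lepmon as lm

spec = lm.SimulationSpec(n_sites=10, n_years=8, n_species=20, trend=1.10)
bundle = lm.simulate_bundle(spec, seed=42)

matrix = lm.annualize(bundle["records"], "sp001")
fits = [lm.fit_trim(matrix, model=k) for k in (1, 2, 3)]
best, none_significant = lm.select_model(fits)
print(best.summary())
```

```
TRIM model 3 (time effects) — sp001
  sites: 10  years: 8  observed cells: 80
  deviance G2 = 315.0224  Pearson X2 = 316.9456  df = 63
  GOF p (X2) = 0.0000  sigma2 = 5.0309  AIC = 189.02
  multiplicative slope m = 1.1260 (SE 0.0170) -> strong increase
```

The time-effects model wins on AIC; the overall multiplicative slope
m̂ = 1.126 says this species' index grew about 12.6% per year, and since
the whole 95% interval (1.093, 1.159) lies above the +5%/year threshold
the trend is categorised a *strong increase*. The counts were drawn
negative-binomial (θ = 5), which is why σ² ≈ 5 inflates the standard
errors and the Poisson goodness-of-fit p is tiny — the categorisation
uses the corrected SE.

The same chain runs from the shell:

```bash
moth simulate --seed 42 --out bundle/
moth trend --counts bundle/counts.csv
moth report --counts bundle/counts.csv --measurements bundle/traits.csv \
            --hosts bundle/hosts.csv --tree bundle/tree.nwk \
            --climate bundle/climate.csv --enso bundle/enso.csv --out report.json
```

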