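# lichenrisk

Critical loads of atmospheric nitrogen and sulfur deposition for epiphytic
macrolichen communities, estimated by 90th-percentile quantile regression.

## The problem

Epiphytic macrolichens are among the most sensitive indicators of air
quality in forests. Community surveys score each plot for six indicator
metrics — total species richness, richness of nitrogen-sensitive
(oligotroph) and sulfur-sensitive species, and summed ocular-abundance
indices for three functional groups (forage, cyanolichen, and matrix
lichens). Because maximal metric values are limited by air quality while
sub-maximal values also reflect climate, substrate, and observer effects,
the dose-response of interest is the **upper (90th percentile) envelope**
of each metric along the deposition gradient, not its mean.

A metric's **critical load (CL)** is the deposition at which its fitted
90%-quantile curve has declined 20% from its value at the minimum observed
deposition. Declines of 20/50/80% delimit *moderate*, *high*, and *very
high* ecological-risk classes.

## What the package provides

- `lichenrisk.quantile` — exact quantile regression by linear programming
  (the pinball-loss LP is solved in its bounded dual form; no wrapped
  third-party quantile fitter), with the Koenker–Machado R1 fit statistic,
  asymmetric-Laplace AIC model comparison, and a pairs bootstrap.
- `lichenrisk.metrics` — the six per-site indicator metrics from raw
  detection tables, species sensitivity ratings from smoothed
  detection-frequency curves, and rarity classification.
- `lichenrisk.critical_loads` — decline curves, anchor tables
  (0/10/20/50/80%), CL inversion, risk classification, and bootstrap
  confidence intervals for the CL.
- `lichenrisk.species_risk` — per-species extirpation thresholds (20/50/90%
  detection-probability declines) and risk classes.
- `lichenrisk.community_stats` — analysis-of-means (ANOM) comparisons of
  group locations (on ranks) and spreads (on absolute deviations from the
  median), gamma diversity, and regional proportion tests.
- `lichenrisk.synthetic` — a seeded survey generator with an exact
  conditional-quantile guarantee and closed-form true critical loads, used
  to validate the whole pipeline end to end.
- `lichenrisk.io_tables` / `lichenrisk.cli` — validated CSV I/O with
  checksummed manifests, and a `lichenrisk` command with subcommands
  `simulate`, `metrics`, `fit`, `cl`, `species-risk`, `group-stats`, `all`.

See [docs/methods.md](docs/methods.md) for the statistical details.

## Worked example

Simulate a 2000-site survey whose true richness curve is
`f(x) = 30 − 3x + 0.05x²` (closed-form CL 2.244 kg N ha⁻¹ yr⁻¹ at a 20%
decline from the 0.2 kg reference), then run the full pipeline:

```bash
lichenrisk all --seed 42 --n-sites 2000 --reps 200 --out demo
```

Output (abridged log):

```
fit: pollutant=N tau=0.90 degree=2 window<=12.0 n=2000/2000
  total_richness: R1=0.365 coef=[30.0419, -2.884, 0.0384]
  cyano_abundance: R1=0.494 coef=[12.6379, -2.4354, 0.1249]
cl: cl_decline=0.20 anchors=(0.0, 0.1, 0.2, 0.5, 0.8) window<=12.0 x_min=0.201 reps=200 seed=42
  cyano_abundance: CL=1.2808848168599056 CI=(1.26, 1.31) unusable_reps=0
  total_richness: CL=2.3148418226655108 CI=(2.18, 2.39) unusable_reps=0
```

`demo/cl/critical_loads.csv` then starts:

```
metric,pollutant,dep_0pct,value_0pct,dep_10pct,value_10pct,dep_20pct,value_20pct,dep_50pct,value_50pct,dep_80pct,value_80pct,critical_load,cl_lo,cl_hi
cyano_abundance,N,0.2,12.0,0.7,11.0,1.3,10.0,3.2,6.0,6.1,2.0,1.3,1.26,1.31
forage_abundance,N,0.2,29.0,1.1,26.0,2.0,23.0,5.3,15.0,10.1,6.0,2.0,1.96,2.14
```

The estimated richness CL (2.31) recovers the configured truth (2.244)
within 3%, and the bootstrap interval covers it. The flat `matrix_abundance`
curve never reaches a 20% decline, so its CL is reported as missing rather
than extrapolated.

The same pipeline is available in Python:

```python
from lichenrisk import (SyntheticConfig, generate_dataset,
                        polynomial_design, fit_quantile_regression,
                        deposition_at_decline)

_, sites, _, truth = generate_dataset(SyntheticConfig(n_sites=2000, seed=42))
X, names = polynomial_design(sites["deposition"].to_numpy(), 2)
fit = fit_quantile_regression(sites["total_richness"].to_numpy(), X, tau=0.9,
                              names=names)
print(deposition_at_decline(fit, x_min=0.2, target=0.20, window=12.0))
# 2.3148...
```

## License

MIT.
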