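# Methods

This document records the statistical model, the defaults and their units,
the synthetic-data generator's scope, and the numerical choices made in the
implementation. Deposition is everywhere in kg ha⁻¹ yr⁻¹ of nitrogen (N)
or sulfur (S).

## 1. Indicator metrics

From a detections table (site × species × ocular abundance code 1–4), a
species table (genus, functional group, regional N and S sensitivity
ratings), and a site table (region, deposition, climate), six per-site
metrics are computed (`lichenrisk.metrics.compute_site_metrics`):

| metric | definition |
|---|---|
| `total_richness` | number of distinct species detected |
| `oligotroph_richness` | species whose region-matched N rating is **strictly** below 4.2 |
| `s_sensitive_richness` | species whose region-matched S rating is **strictly** below 2.7 |
| `forage_abundance` | sum of abundance codes ≥ 3 over forage (pendant/shrubby fruticose) species |
| `cyano_abundance` | sum of abundance codes ≥ 3 over cyanolichen species |
| `matrix_abundance` | sum of abundance codes ≥ 3 over matrix (foliose green-algal) species |

Conventions: sensitivity cutoffs are strict inequalities; a species rated
only in the other region does not count toward a sensitive-richness metric;
sites with fewer than 5 species are flagged `excluded_low_richness` but not
dropped by the metric computation itself; sites with no detections score 0.

**Sensitivity ratings** for unrated species are the deposition at the peak
of a Nadaraya–Watson (Gaussian-kernel) smooth of detection frequency on
log-deposition, evaluated on a 200-point grid, with Silverman's bandwidth
(an IQR guard prevents zero bandwidth). Species with fewer than 8
detections, or with a degenerate gradient, are left unrated. **Rarity**:
detection in < 1% of sites is *rare*, > 10% is *common*.

## 2. Quantile regression (`lichenrisk.quantile`)

Each metric's conditional 90th percentile is modeled as a polynomial in
deposition (default degree 2, raw powers so coefficients are directly
invertible), optionally with additive climate covariates. The fit
minimizes the pinball loss ρ_τ(u) = u(τ − 1[u<0]), τ = 0.9.

The solver is implemented here, not wrapped: the problem is solved exactly
as the bounded **dual linear program**

```
max  yᵀd   subject to  Xᵀd = 0,   −(1−τ) ≤ dᵢ ≤ τ,
```

via `scipy.optimize.linprog(method="highs")`; the coefficient vector is the
negated vector of equality-constraint marginals and the optimum equals the
primal pinball objective (checked by strong duality on every fit). The dual
form has n box-constrained variables and p equality constraints and fits
n = 2000, p = 3 in ~14 ms, which makes the bootstrap suites tractable on a
single CPU. At an optimal basic solution the fitted curve interpolates p
observations; residual-sign counts satisfy #(u<0) ≤ τn and #(u>0) ≤ (1−τ)n.
Sign counts use a relative tolerance of 1e-9 because interpolated
observations carry residuals at solver precision rather than exact zeros.
`statsmodels` `QuantReg` is used in the test suite only, as an independent
cross-check oracle.

Goodness of fit is **R1 = 1 − V(model)/V(intercept-only)** (undefined when
the null objective is zero). Model comparison uses the asymmetric-Laplace
pseudo-likelihood AIC, `AIC = −2n(log(τ(1−τ)) − 1 − log(V/n)) + 2p`; a
richer nested model is preferred only when its AIC is lower by more than
**25** — a deliberately stringent evidence bar suited to national-scale
survey data (configurable). Uncertainty comes from a **pairs (site-level)
bootstrap**: sites are resampled with replacement and the model refit;
rank-deficient resamples are dropped and counted, and more than 10%
dropped replicates is an error.

## 3. Critical loads and risk classes (`lichenrisk.critical_loads`)

With f the fitted quantile curve and x_min the minimum observed deposition,
the decline at x is `1 − f(x)/f(x_min)`, clipped to [0, 1]. The
**critical load** is the smallest deposition in the modeling window at
which the decline reaches **20%**; anchor tables also report 0/10/50/80%.
Anchor metric values are `f(x_min)·(1 − decline)` rounded half away from
zero (they are counts). Risk classes: decline < 20% *low*, [20, 50%)
*moderate*, [50, 80%) *high*, ≥ 80% *very high* (the upper class wins at a
boundary).

Inversion uses a 2048-point bracketing grid followed by Brent's method
(tolerance 1e-6 kg). A curve that never reaches the target within the
window yields `None` (tabulated as missing), never an extrapolation. The
CL confidence interval is the percentile 2.5/97.5% interval of the
per-replicate inverted CLs; replicates that never reach the decline are
counted as unusable, and more than 50% unusable is an error. Default
modeling windows are ≤ 12 kg N and ≤ 20 kg S.

Per-species **extirpation thresholds** are read from the descending limb of
the smoothed detection-frequency curve at 20/50/90% declines from the peak
(linear interpolation between grid points); a species whose curve never
drops that far has a blank threshold, which caps its attainable risk class,
and monotonically increasing species are flagged as increasers.

## 4. Community statistics (`lichenrisk.community_stats`)

Group locations are compared by **ANOM on ranks** (joint ranking, then
analysis of means) and spreads by **ANOM on absolute deviations from the
group median** (a Levene-type statistic). Decision limits are

```
grand mean ± c · s · sqrt((N − nᵢ)/(N·nᵢ)),  s = sqrt(MS_error),
c = t(1 − α/(2k), N − k)
```

i.e. **Bonferroni-adjusted** t critical values rather than exact
simultaneous ANOM tables; this is conservative, and simulation in the test
suite shows a realized family-wise false-flag rate of ≈ 0.04–0.05 at
α = 0.05 with six groups. Groups with n < 2 are excluded with a warning;
constant groups produce no flags. Two-region proportion comparisons use a
standard two-proportion z-test.

## 5. Synthetic data generator (`lichenrisk.synthetic`)

The generator exists to validate the estimators against a known truth, not
to emulate any real survey. In **metric mode** each metric is drawn as

```
Y = round_half_away( f(x) · U ),   U ~ Uniform(0, 1/0.9),
```

so the conditional 90th percentile of the pre-rounding value is exactly
f(x) — the quantity the τ = 0.9 fit estimates — with closed-form true
critical loads via the quadratic formula
(`true_deposition_at_decline`). Default truth for total richness is
`f(x) = 30 − 3x + 0.05x²` on x ∈ [0.2, 12], giving CL = 2.2439 kg at a 20%
decline from the 0.2 kg reference. The deposition gradient is capped at
12 kg (the N modeling window) so all default curves stay positive.

In **species mode**, per-species detection probabilities are Gaussian bumps
in log-deposition around a true optimum, and abundance codes come from an
ordinal cut of a decaying latent, after which metrics must be computed by
`compute_site_metrics` (an independent naive tally, `tally_metrics`, is
kept for cross-checking). Not emulated: spatial autocorrelation, observer
effects, plot revisits, and covariance between metrics beyond their shared
deposition dependence.

Identical configurations (including seed) reproduce all tables
bit-for-bit.

## 6. Numerical and tabulation notes

- LP feasibility/optimality is delegated to HiGHS; a strong-duality check
  (1e-8 absolute / 1e-9 relative) guards the recovered coefficients.
- Anchor depositions in tabulated output are rounded to one decimal and
  metric values to integers **after** all computation; recomputing one
  rounded quantity from another rounded quantity can therefore disagree
  with the table by one unit in the last digit. In particular, an
  abundance index tabulated for a worked example should be checked against
  the plain sum of its qualifying codes, which is what this package
  reports.
- Reference depositions: the reference x_min is the minimum *observed*
  deposition of the dataset being fit. Published-style anchor tables
  sometimes mix a 0.1 kg tabulation origin with a different observed
  minimum; this package always uses the dataset's own x_min and records it
  in the output.

## 7. Limitations

- Critical loads are never extrapolated beyond the modeling window; flat
  or increasing metrics have no CL by construction.
- The asymmetric-Laplace AIC is a pseudo-likelihood device; the ΔAIC > 25
  bar is a policy choice, not a calibrated test.
- Bonferroni ANOM limits are conservative relative to exact simultaneous
  limits, mildly under-flagging at small k.
- The bootstrap CI for the CL is a percentile interval; it inherits the
  usual first-order accuracy of percentile intervals and degrades when
  many replicates fail to reach the target decline.
- Sensitivity ratings from kernel smooths depend on bandwidth; Silverman's
  rule is a default, not an optimum, and species with < 8 detections are
  deliberately left unrated.
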