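# Methods

This note records the statistical model behind each stage, the defaults
and why they were chosen, what the synthetic study system does and does
not emulate, and the numerical conventions a reimplementation would need.

## Edge definition and shift estimation

The northern range edge at quantile τ is the minimizer of the check loss
Σ ρ_τ(y_i − q), ρ_τ(u) = u·(τ − 1[u<0]), over a species' presence-cell
northings. Because time period enters only as a two-level factor, the
quantile-regression fit decomposes exactly into per-period sample
quantiles; the package therefore computes order statistics directly and
verifies them against an exhaustive check-loss grid search in the tests.

*Tie convention.* When n·τ is an integer the loss is minimized on the
interval [y_(nτ), y_(nτ+1)]; the lower endpoint is returned, matching the
vertex solutions of linear-programming quantile fits. This matters on
gridded data, where the two endpoints can differ by a whole cell (10 km).

*Confidence intervals.* 95% CIs use a stratified percentile bootstrap
(resampling within each period independently, B = 1000, seeded). The CI
is widened, if necessary, to contain the point estimate so that interval
and point never disagree. Calibration under a continuous no-shift null at
n = 50 per period is slightly conservative (~97% empirical coverage of
zero); on strongly gridded data with few distinct northings the bootstrap
inherits the usual lumpiness of quantile resampling, which is one reason
species below 5 presences per period are excluded outright (a τ = 0.9
quantile is meaningless below that support; threshold configurable).

*Replicates.* Point estimate and both CI endpoints are arithmetic means
over the five balanced replicates. Shift classification (northward /
southward / none) uses the averaged CI against zero.

*Speeds.* Group summaries convert mean shift to km/yr using caller-
supplied period mid-years (defaults mirror the bird-atlas 1981.5→2008 and
Lepidoptera 1994→2015 spans). Because the span is constant within a
group, the mean of per-species speeds equals the mean shift divided by
the span; only that convention is reported.

## Effort balancing

Recording effort is equalized between periods by subsampling the pooled
second-period presences, without replacement, down to the first-period
total within each of five equal-width latitudinal zones, independently
five times. T1 is never modified and nothing is upsampled.

Two properties define what this correction can and cannot do:

- Under a no-shift null with spatially uniform (or zone-scale) effort
  inflation, balancing removes the poleward bias entirely; the validation
  experiment (200 zero-shift species, T2 effort 3× inflated and doubling
  from south to north in five zone-width bands) shows a balanced mean
  estimated shift statistically indistinguishable from zero while the
  unbalanced mean is ~+9 km.
- Effort variation *within* a zone is invisible to the correction: the
  subsample is drawn uniformly from a zone's presences, so any intra-zone
  latitudinal tilt of effort survives. Finer gradients therefore leave a
  residual bias of order the within-zone tilt; more zones shrink it.
- When true shifts are present, the northernmost zones gain genuinely
  colonized cells in T2, so matching them to their (small) T1 totals
  removes signal as well as bias: estimated shifts are conservative
  (about 55% of truth under the default synthetic conditions) while
  remaining strongly rank-correlated with truth (r ≈ 0.88). Analyses of
  *which species* shift most are therefore much more robust than the
  absolute shift magnitudes.

Subsampling operates on deduplicated presences by default, consistent
with equalized presence totals per zone; a record-level variant (subsample
raw observations, then grid) is provided for sensitivity analysis. The
species delimitation uses the unweighted mean of T1 presence northings as
the distribution center (median available via config) and removes species
with center ≥ 7,000,000 m N.

## Niche metrics

Metrics are empirical summaries over the climate values of a species'
occupied continent-grid cells: mean, SD and CV per variable, plus range
size as the count of occupied cells. SD is the sample SD (n − 1), the
convention of common statistical software; the population SD is available
via `ddof=0`. CV divides by the mean in Kelvin for MAT (°C + 273.15) so
that near-zero Celsius means cannot explode or flip the sign of relative
breadth. Cells missing a value are dropped per variable, not per species.

The regression weight for a species is the inverse of its 95% CI *width*
(upper − lower), the most direct reading of "inverse of the confidence
interval"; an inverse-half-width option exists and only rescales all
weights by 2, which the fitting conventions below make irrelevant.

## Weighted regression and model selection

Continuous covariates are z-scored (sample SD); factors are treatment-
coded against the first level of a caller-declared order (alphabetical by
default). The fit minimizes Σ w_i (y_i − x_iᵀβ)², with

- log-likelihood ℓ = ½[Σ log w_i − n(log 2π + 1 + log(RSS_w/n))],
- AIC = −2ℓ + 2(k + 1), counting the error variance as a parameter,
- R² = 1 − RSS_w/TSS_w with TSS_w about the weighted mean,
- adjusted R² = 1 − (1 − R²)(n − 1)/(n − k),
- predicted R² = 1 − PRESS_w/TSS_w with
  PRESS_w = Σ w_i (e_i/(1 − h_ii))² from the leverages of the weighted
  design (negative values are legal and occur for weak models).

These conventions reproduce `lm`/`logLik`/`AIC` in R exactly (verified
against an independent R fit during development and against statsmodels
WLS and direct numerical loss minimization in the tests). Note the
Σ log w_i term makes ℓ, and hence AIC, invariant under rescaling all
weights by a constant — the substantively correct behavior, since weights
here encode only *relative* precision.

Best-subsets enumeration fits all 2^p subsets (factors as blocks,
intercept-only included), flags the per-size best by R², and the
parsimony rule chooses the smallest per-size best whose AIC is within
δ = 2 of the global minimum — a larger model must "buy" its extra
parameters with more than 2 AIC units. Replaying this rule on the three
published per-size AIC vectors reproduces the published choices (sizes 3,
3 and 1). Drop-one tables refit on identical rows and report ΔDf, the
increase in weighted RSS, and the reduced model's AIC under the same
likelihood convention (R's `drop1` prints AICs on the additive-constant
`extractAIC` scale; differences between models agree). Diagnostics:
Shapiro–Wilk on √w-scaled residuals, Breusch–Pagan against the model
design, generalized VIFs per block via the correlation-determinant
formula, and Cook's distances flagged above 4/n. Prediction profiles vary
one continuous covariate from its observed minimum to maximum in original
units, hold the others at their means, and produce one curve per
combination of factor levels.

## Synthetic study system

The generator emulates the *statistical* structure the pipeline assumes,
not real geography:

- a 20 × 110-cell grid of 10-km cells spanning an 1,100-km latitudinal
  gradient (northings 6.6–7.7 × 10⁶ m);
- species edges uniform in 6.9–7.35 × 10⁶ m, every cell south of the edge
  occupied independently with probability 0.5 (one realization per
  species, shared between periods, so a zero shift implies identical
  supports); the T2 edge is the T1 edge plus 1,000 × true shift;
- detection of an occupied cell with a per-year rate per period (defaults
  0.1/yr in T1 1992–1996 and 0.3/yr in T2 2013–2017, i.e. 3× inflation),
  optionally tilted south-to-north, linearly or in zone-width bands;
  records fall at cell centroids;
- true shifts `β₀ + Σ β_j z(covariate_j) + N(0, σ)` with defaults β₀ =
  30 km, β(thermal breadth) = −30 km/SD, σ = 20 km — a strong, simple
  one-predictor structure whose recovery is checked at n = 240;
- a 50 × 60-cell continent grid of 50-km cells with MAT falling 17 →
  −5 °C northward (noise SD 0.8), noisy PREC/SWC gradients, and GDD5 =
  max(0, 150·MAT + 500) as a correlated alternative thermal variable;
- a continent atlas drawn per species by Gaussian niche-kernel weighted
  sampling of cells (target range size 500–2,500 cells). Because the
  kernel is conditioned on what the continent's covarying climate offers,
  measured niche metrics track the species' nominal parameters tightly in
  correlation (r > 0.9) but not cell-exactly — as with real atlases, the
  realized niche is narrower than the fundamental one;
- Lepidoptera-style traits: overwintering mode with frequencies
  0.4/0.15/0.3/0.15 (adult/egg/larva/pupa), voltinism 0.7/0.3, lognormal
  body size.

Everything is deterministic given a seed; pipeline stages derive
sub-seeds by hashing (master seed, stage label), so adding a stage never
perturbs another stage's draws. What passing tests on this system do
*not* show: robustness to spatially autocorrelated occupancy, coastline
truncation of ranges, taxonomic error, or effort patterns correlated with
individual species — none of which the generator models.

## Problem sizes of the shipped experiments

Chosen to characterize the estimators well while keeping the full suite
and the acceptance script comfortably re-runnable: 200 species for the
pipeline and bias experiments, 240 species × 100 runs for coefficient
recovery, 1,000 simulations × B = 1,000 for bootstrap calibration, and
the exhaustive quantile oracle over all ~18.6 k multisets of size ≤ 12
from a six-value alphabet at two τ values.

## Known limitations

- Balancing attenuates true shift magnitudes (see above); reported
  shifts are conservative wherever second-period effort must be
  subsampled hard in the leading-edge zones.
- The percentile bootstrap is mildly conservative for extreme quantiles
  at moderate n and is not corrected for grid discreteness.
- The predicted-R² definition under weights follows the leverage-based
  weighted PRESS; other software may use slightly different weighted
  PRESS definitions.
- Phylogenetic non-independence among species is not modelled anywhere in
  the pipeline.
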