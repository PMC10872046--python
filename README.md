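# edgeshift

Tools for quantifying recent poleward shifts of species' northern range
edges from opportunistic occurrence data, and for testing whether the
breadth of a species' climatic niche predicts how far its edge has moved.

## Who this is for

Macroecologists working with atlas-style presence data across two
observation periods face two standard problems: recording effort usually
explodes between periods (so naive edge comparisons are biased poleward),
and per-species edge estimates carry very different uncertainties (so
downstream regressions need weights). This package implements a complete,
tested pipeline for that setting, together with a synthetic study system
with known ground truth so every stage can be validated end to end.

## The method

1. **Presence gridding.** Occurrence records are reduced to
   species × 10-km-cell × period presences on a planar grid; species whose
   first-period distribution center lies at or above a northing threshold
   (default 7,000,000 m, the Finnish uniform coordinate system) are
   removed so that only species with a genuine leading edge in the study
   area remain.
2. **Effort balancing.** The study extent is split into five latitudinal
   zones and second-period presences are randomly subsampled, without
   replacement and pooled across species, down to the first-period total
   in each zone — repeated five times to give five balanced replicates.
3. **Edge shifts.** The northern edge is the τ-quantile (τ = 0.9 and
   0.75) of a species' presence northings. With time period a two-level
   factor, quantile regression reduces to per-period sample quantiles of
   the check loss ρ_τ(u) = u·(τ − 1[u<0]), so the shift is
   Δ = q_τ(T2) − q_τ(T1), averaged over the five replicates. 95% CIs come
   from a stratified percentile bootstrap (B = 1000), and species are
   classified northward/southward/none by whether the CI excludes zero.
4. **Niche metrics.** From a continent-scale occupancy grid and cell
   climate values, each species gets the mean (for temperature, the
   species temperature index, STI), SD (absolute niche breadth) and
   CV = SD/mean (relative breadth, Kelvin basis for temperature) of MAT,
   GDD5, PREC and SWC, plus range size (occupied cells).
5. **Shift regression.** Shift (km) is regressed on eight candidate
   predictors (thermal/moisture niche mean and breadth, overwintering
   mode, generations per season, body size, range size) by weighted least
   squares with weights 1/CI-width and z-scored continuous covariates.
   All 2^8 = 256 subsets are fitted; among the per-size best models (by
   R²), the smallest model within 2 AIC units of the minimum is selected.
   Drop-one tables, residual/collinearity/influence diagnostics and
   prediction profiles describe the final model.

## Worked example

The numbered scripts under `analysis/` run the full study on synthetic
data (200 species whose true shifts follow
`30 − 30·z(thermal breadth) + N(0, 20)` km):

```sh
python analysis/01_simulate.py
python analysis/02_prepare_occurrences.py
python analysis/03_estimate_edge_shifts.py
python analysis/04_niche_metrics.py
python analysis/05_fit_shift_models.py
python analysis/06_validation_experiments.py
```

The model-fitting step prints, for one representative run:

```
enumerated 256 candidate models over 8 predictors
chosen model (1 predictors, AIC 1840.2, R2 0.516): Tbreadth
coefficients (response km, continuous predictors standardized):
  Intercept                   17.71  (p = 4.3e-21)
  Tbreadth                   -24.17  (p = 4.5e-33)
```

The selection recovers the generating structure: thermal niche breadth is
the single chosen predictor, with a negative coefficient — species with
narrower thermal niches shifted further north. The magnitude (−24 km/SD
against the generating −30) and the intercept (17.7 against the true mean
shift of 29.6 km) are attenuated because zone balancing, which removes
effort bias exactly under the no-shift null, subsamples genuinely
colonized northern cells hardest; the validation script quantifies both
effects with known truth:

```
bias removal: balanced mean -0.53 km (SE 1.15), unbalanced +9.95 km
thermal breadth selected in 100% of runs; mean coefficient -29.7 km/SD (true -30.0)
bootstrap 95% CI covered the true zero shift in 95.7% of 1000 simulations
```

A single config-driven entry point runs the same pipeline in one go:

```sh
edgeshift run --config config.yaml     # or: edgeshift prep|edges|niche|model
```

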