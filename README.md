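# sdmbias

Presence-only species distribution modelling with spatial sampling-bias
correction and subgroup (sex) ratio estimation.

## The problem

Presence-only records — sign locations from wildlife surveys with no
confirmed absences — are usually collected with spatially uneven effort:
observers follow routes they choose themselves, concentrating on habitat
they expect to be productive. When population subgroups differ in habitat
preference (a classic example is Capercaillie, *Tetrao urogallus*, where
males use more open forest than females), this spatial bias does double
damage: it distorts the estimated habitat coefficients, and it skews the
apparent sex ratio, because effort concentrates in the habitat of one sex.

`sdmbias` is a simulation and estimation toolkit for studying and
correcting this problem. It provides:

- **Synthetic landscapes** — spatially autocorrelated, standardized
  covariate rasters with prescribed pairwise correlations, and
  habitat-biased "subjective" observer trajectories emulating GNSS survey
  tracks (plus ESRI ASCII / GeoJSON / CSV I/O);
- **A sex-structured virtual species** — per-sex log-linear intensity
  surfaces ln λ(s) = β₀ + Σᵢ xᵢ(s)βᵢ realized as inhomogeneous Poisson sign
  counts, with the male intercept calibrated in closed form so the expected
  sex ratio (female share of total intensity) hits a target exactly;
- **Virtual surveys** — random points, systematic transects, and subjective
  trajectories, with distance-decay detection p(d) = g(d)/g(0) and binomial
  thinning of counts into presence-only records;
- **Presence-only SDM fitting** — the Maxent-equivalent infinitely weighted
  logistic regression (linear features), with two bias corrections:
  *targeted background* (background points carrying the same spatial bias
  as the observations, so the bias cancels) and a *distance-to-trajectories
  covariate*;
- **Detection-corrected estimation** — expected total signs under complete
  sampling, N_tot = N_obs / Σⱼ μⱼ p_obs,ⱼ, sign-density maps λⱼ = μⱼ N_tot / aⱼ,
  and sex ratios N_tot,f / (N_tot,f + N_tot,m);
- **A replicated experiment driver** — parameter-recovery bias, Spearman
  map correlation, cross-validated AUC, and sex-ratio estimates across
  designs × corrections × replicates.

## Worked example

Simulate a systematic-transect survey of the virtual species, fit a
bias-corrected SDM for each sex, and estimate the sex ratio:

```python
import numpy as np
import sdmbias as sb

stack = sb.default_landscape(seed=0)          # 145x145 cells of 25 m
female = sb.default_params("female")          # slopes -0.9, -0.8, +1.0
male = sb.calibrate_male_intercept(stack, female,
                                   sb.default_params("male").slopes, 0.5)
lam_f = sb.compute_intensity(stack, female)
lam_m = sb.compute_intensity(stack, male)

det = sb.DetectionModel.half_normal(10.0, truncation=300.0)
design = sb.systematic_transects(stack.reference.extent, spacing=400.0, seed=0)
dist = sb.distance_to_trajectories(stack.reference, design)
rec_f = sb.thin_to_presences(sb.realize_counts(lam_f, seed=1), design, det,
                             seed=2, sex="female", distance=dist)
rec_m = sb.thin_to_presences(sb.realize_counts(lam_m, seed=3), design, det,
                             seed=4, sex="male", distance=dist)

bg = sb.targeted_background(design, det, n=10_000, seed=5,
                            extent=stack.reference.extent)
res = sb.PresenceOnlySDM(rec_f, bg, stack).fit()
print(res.summary())
```

prints

```
Presence-only SDM (weighted logistic / point-process fit)
  correction: targeted   presences: 87   background: 10000 (targeted)
  log-likelihood: -1179.43
  term              coef   std err
  intercept     -15.3444    0.2237
  slope          -0.9334    0.1199
  canopy         -0.8613    0.1228
  simpson         0.9765    0.0775
```

The 87 observed female signs (of ~1,390 simulated) recover the generating
slopes (−0.9, −0.8, +1.0) within one standard error. Continuing to the
detection-corrected sex ratio:

```python
mu_f = res.predict_relative_abundance()
mu_m = sb.PresenceOnlySDM(rec_m, bg, stack).fit().predict_relative_abundance()
p = sb.detection_grid("detection-density", distance=dist, model=det)
est = sb.sex_ratio_from_models(len(rec_f), len(rec_m), mu_f, mu_m, p, p)
print(est.n_tot_female, est.n_tot_male, est.ratio)
```

gives N_tot ≈ 1413 females and 1338 males — an estimated proportion of
females of **0.514** against the calibrated truth of 0.5, from a survey
that detected only ~6% of the signs. The female relative-abundance map
rank-correlates with the true intensity at ρ = 0.999.

The full replicated study (three designs × three corrections × sex-specific
and generic models, 100 replicates) runs with

```sh
sdmbias experiment --seed 1 --out results/ --plots
```

and writes long-format results plus summary tables of coefficient
estimates, Spearman map correlations, and sex-ratio quartiles.

## Layout

- `src/sdmbias/grid.py` — rasters, covariate stacks, standardization, I/O
- `src/sdmbias/landscape.py` — Gaussian-random-field covariates, subjective trajectories
- `src/sdmbias/species.py` — sex-specific intensities, calibration, Poisson counts
- `src/sdmbias/survey.py` — designs, distance rasters, detection, thinning
- `src/sdmbias/sdm.py` — backgrounds and the weighted-logistic SDM (Model/Results)
- `src/sdmbias/estimation.py` — detection surfaces, N_tot, sign density, sex ratios
- `src/sdmbias/evaluation.py`, `experiment.py` — metrics and the replicated driver
- `docs/methods.md` — model details, defaults, and known limitations
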