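# Methods

This note documents the models, the default study conditions, the numerical
choices, and what the synthetic experiments do and do not demonstrate.

## Species model

Each sex follows an independent inhomogeneous Poisson point process on a
raster of S cells. With standardized covariates x_i(s) (mean 0, sd 1 over
non-missing cells), the intensity is

    ln λ(s) = β₀ + Σ_i x_i(s) β_i ,

and the sign count in cell j is Poisson(λ_j). The shipped default
parameterization gives the sexes contrasting preferences:

| sex    | slope | canopy | simpson | intercept |
|--------|------:|-------:|--------:|----------:|
| female | −0.9  | −0.8   | 1.0     | −4.0      |
| male   | −0.2  | 0.9    | −0.9    | −3.55     |

The tabulated male intercept applies to the landscape it was originally
tuned on; on any other landscape `calibrate_male_intercept` replaces it with
the closed form

    β₀ᵐ = ln Σ_s λ_f(s) − ln Σ_s exp(Σ_i x_i(s) β_i,m) + ln((1−r)/r) ,

which makes the expected female share Σλ_f/(Σλ_f+Σλ_m) equal the target r
exactly (no iteration, no tolerance). Intensities are a sanity diagnostic:
per-cell values should mostly lie below ~2; the generator does not enforce
this because it depends on the covariate field.

## Synthetic landscape

Covariate layers are stationary Gaussian random fields with an exponential
correlogram exp(−h/range), simulated by circulant embedding on a 2× padded
torus (negative embedding eigenvalues, a discretisation artefact, are
clipped). Layers are standardized, empirically whitened, and re-mixed with
the Cholesky factor of the target correlation matrix, so the realized
pairwise Pearson correlations equal the target exactly rather than only in
expectation. Defaults: 145×145 cells of 25 m (≈13 km²), three layers named
slope, canopy, simpson with low pairwise correlations (0.21, 0.18, 0.12) —
the regime of weakly correlated LiDAR-derived terrain and vegetation
variables. The autocorrelation range (default 300 m) is a stand-in: real
LiDAR covariates have no single published correlogram; it is exposed in the
configuration.

## Surveys and detection

Three designs:

- **random** — n i.i.d. uniform points (default 2,000); a cell is sampled
  if it contains at least one point, and detection is 1 in sampled cells
  and 0 elsewhere;
- **systematic** — parallel transects at fixed spacing (default 400 m,
  ≈32 km total on the default landscape) with a uniformly random offset;
- **subjective** — a correlated random walk (default 31.2 km of 25 m steps)
  whose step-direction choice up-weights a habitat-preference surface via a
  softmax with weight `bias_strength` plus a heading-persistence term. In
  the default study the preference surface is the male log-intensity, so
  survey effort concentrates in male-preferred habitat — the mechanism that
  biases the observed sex ratio.

For trajectory designs, observation is distance-limited: a sign at cell
distance d_j (minimum point-to-segment distance from the cell center to any
trajectory) is detected with probability p(d_j) = g(d_j)/g(0), where g is a
distance density with finite truncation (default 300 m). Counts are thinned
cell-wise by Binomial(count_j, p_j) draws, and observed signs become
presence-only records at cell centers, duplicates retained.

The true g in the default study is half-normal with σ = 10 m. The scale was
set by observation-count accounting: a 400 m transect grid detecting ~70 of
~1,300 signs implies a mean detection of ~0.06 across the 0–200 m distance
range, i.e. a decay scale near 10 m — the regime where signs are found
essentially on or beside the track. The half-normal shape (rather than
exponential) deliberately keeps the distance-covariate correction model,
which is log-linear in d, misspecified: the relative strength of the two
corrections depends on how well each represents the true decay, and a
log-linear truth would make the distance model exact and erase that
contrast. `fit_detection_model` supports exponential and half-normal
closed-form MLEs and an empirical log-density spline (cubic B-spline
Poisson regression on binned distances, emulating a logspline estimate) for
use with real distance samples.

## SDM and corrections

Maxent with linear features is fitted as an infinitely weighted logistic
regression: presences weight 1 against background points weight W (default
10,000). At that weight the slope estimates agree with a Berman–Turner
down-weighted Poisson quadrature fit on the same points to ~1e-5 (the
quadrature fit serves as an independent oracle in the tests, never as the
implementation). No regularization by default; a ridge penalty is available
as a separation rescue. The distance covariate enters as d/100 for
conditioning and β_d is reported per metre.

Background strategies (10,000 points, fixed across replicates within a
scenario):

- **uniform** — uniform over non-missing cells (no correction);
- **targeted** — position uniform-by-length along the trajectories, offset
  distance drawn from g, side uniform; out-of-extent draws are rejected.
  The empirical distance distribution of the points matches g (KS ≤ 0.05 at
  n = 10,000 against a single transect).

Relative abundance is the normalized raw output μ_j = exp(Σ x_i β̂_i)/Σ
(intercept cancels); for distance-corrected fits the distance term is set
to zero, i.e. contributes exp(0).

## Estimation

Detection surfaces p_obs,j: the distance density g(d_j)/g(0) for the
uncorrected and targeted models; exp(β_d d_j), capped at 1, for the
distance-covariate model (a positive β̂_d triggers a warning — it signals a
fitting problem); a binary sampled-cell indicator for the random design.
The expected total number of signs under complete sampling inverts the
expected observation count:

    N_tot = N_obs / Σ_j μ_j p_obs,j ,

so p ≡ 1 gives N_tot = N_obs and p ≡ 0.5 gives 2 N_obs. (The quotient — not
a product — is forced by this complete-sampling limit.) Sign density is
λ_j = μ_j N_tot / a_j in signs/ha, conserving Σ λ_j a_j = N_tot. Sex ratios
are proportions of females, from raw observation counts or from per-sex
N_tot.

## Replicated experiment

`run_experiment` fixes one landscape, one design per kind, one detection
model, and one background set per scenario, then redraws the Poisson
realization and thinning per replicate (default 100). Per replicate ×
design × correction it fits female, male, and pooled (generic) models and
records coefficient estimates and biases (signed, estimate − truth;
summaries also support magnitudes since sign conventions vary in reported
comparisons), Spearman rank correlation between predicted relative
abundance and the generating intensity (sex-specific models against their
own sex, generic against both), 10-fold cross-validated AUC against an
evaluation background drawn from the same distance distribution as the
targeted background but independently of the fitting background, and the
four sex-ratio estimates. Randomness derives from a single master seed via
spawned substreams; identical config + seed reproduces tables bit-for-bit.

AUC folds are stratified random over presences and background with a fixed
seed; the reported variance is the empirical between-fold variance. Folds
without presences are skipped with a warning.

Default problem sizes (145×145 cells, 100 replicates, 10,000 background
points) complete in a few minutes on one CPU; the experiment smoke tests
use a 40×40 landscape with 2 replicates.

## What the synthetic study does and does not show

The generator reproduces the structural features that drive the bias
phenomenon — contrasting per-sex habitat coefficients, low covariate
cross-correlation, spatial autocorrelation, sharply distance-limited
detection, and effort concentrated in one sex's habitat — and the default
conditions yield observation counts per sex and design in the realistic
range (tens to ~100 per replicate). It does not emulate observer
heterogeneity, temporal effort variation, imperfect sex assignment,
movement or clustering of individuals (counts are independent Poisson), or
real terrain. Passing recovery tests therefore demonstrate the estimators'
behavior under the assumed observation model, not robustness to those
further complications.

Known limitations:

- With a single fixed trajectory layout per study, chance correlation
  between the distance raster and autocorrelated covariates does not
  average out across replicates; scenario-level results (especially for the
  distance-covariate correction) vary visibly between master seeds. The
  distance-corrected sex ratio on the systematic design sits at the edge of
  a ±0.05 band around truth for this reason, while the targeted correction
  is stable and accurate.
- The distance-covariate correction inflates N_tot for both sexes by a
  sex-asymmetric factor when the true decay is not log-linear; only the
  asymmetry (not the common factor) reaches the ratio.
- Per-sex presence samples under the subjective design can be small
  (~20 records); individual replicate fits are then noisy by design, and
  conclusions rest on replicate summaries.
- The empirical-spline detection fit uses 20 bins and a fixed 4-column
  cubic B-spline basis; it is meant for smooth unimodal decays, not for
  multimodal distance distributions.
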