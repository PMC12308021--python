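# Methods

This note documents the models, numerical choices and limitations of
`numtune`'s numerosity pRF analysis, and what the synthetic-data
experiments do and do not establish.

## Stimulus design

One run presents numerosities in the fixed cycle 1–2–3–4–5–20–5–4–3–2–1–20.
Small-numerosity blocks contain six 300 ms presentations alternating with
400 ms blanks (4.2 s per block); 20-dot baseline blocks contain 24
presentations (16.8 s).  Four cycles span 302.4 s of a 304.5 s run
(145 volumes at TR 2.1 s); the trailing 2.1 s is modeled as rest.  Ten
percent of presentations are catch trials (white dots).  Catch trials
keep their numerosity and enter the tuning model like any other event —
only dot color differs — and the behavioral hit rate counts a catch as
detected if a button press falls within a response window (default
1.5 s) of its onset.

## Forward model

The neuronal response is event-locked: z(t) equals the log-Gaussian
tuning response to the presented numerosity during each 300 ms
presentation and zero in gaps and rest (a block-sustained variant that
holds the response through within-block gaps is available via
`block_sustained=True`).  Microtime resolution is dt = 0.05 s, chosen
because it divides both the 300 ms presentation and the 400 ms gap
exactly, so boxcars need no resampling.  The HRF is the canonical
double-gamma (response delay 6 s, undershoot delay 16 s, dispersions 1,
undershoot ratio 6, 32 s support), peak-normalized to 1 so that the
scaling coefficient β is expressed in percent signal change.  Predicted
signals are sampled at t_k = k·TR + 1.025 s, matching slice-time
correction to the middle of the acquisition window.  Because z(t) is a
tuning-weighted sum of six per-numerosity boxcars, the grid search
convolves each boxcar once and obtains all 5340 grid predictors by a
single matrix product.

## Signal preparation

Order is fixed: percent signal change per vertex and run
(100·(y−mean)/mean), then regression of 12 confounds per run (six motion
parameters, white-matter/CSF/global means, three discrete-cosine drift
regressors; intercept always included), then averaging across runs.
The cosine basis is the DCT-II with the constant term excluded, one
standard choice for slow-drift modeling; its columns are exactly
orthogonal and zero-mean.  Vertices with zero temporal mean or
non-finite values are masked and propagate as missing rows through every
later stage.  Split halves are the odd (1, 3, 5, 7) and even
(2, 4, 6, 8) runs in 1-based acquisition order.

## Estimation

The grid covers μ ∈ [0.8, 5.2] (step 0.05, extending beyond the
presented 1–5 so edge preferences are not clipped) and σ_log ∈
[0.05, 3.0] (step 0.05), i.e. FWHM 0.12–34.17 at μ = 1 and 0.59–170.9 at
μ = 5.  For each combination, β and β₀ come from OLS and the Gaussian
maximum log-likelihood is −n/2·(ln(2π·RSS/n)+1); the argmax over the
grid equals the argmin of RSS.  Exact ties break toward smaller σ_log,
then smaller μ (sharper tuning preferred); ties essentially arise only
for degenerate predictors.  Serial correlations are ignored (plain OLS).

Cross-validation refits β and β₀ on the test half, so the tested model
has p = 2 free parameters — tuning parameters come from independent
data.  cvR² is the mean of the two test-half coefficients of
determination, reported unclipped (it may be negative).  Reported
(μ̂, ω̂) come from the fit to the all-runs average.  A linear-space
Gaussian tuning variant is available (`tuning="linear"`); its σ_lin
grid spans the same FWHM range as the log grid at μ = 1.

## Selection and surface analysis

A vertex is numerosity-selective if β̂ > 0, 1 ≤ μ̂ ≤ 5, and cvR² exceeds
the threshold obtained by inverting the F(p−1, n−p) quantile at
1 − α/n_vertices with n = 145, p = 2 (α = 0.05, Bonferroni over the
hemisphere's vertices; 0.1625 for 100,000 vertices).  The averaged cvR²
is thresholded; per-half gating is not applied.  Clusters are connected
components of selected vertices over mesh edges; cluster area sums
native-space pial triangle areas over triangles whose three vertices are
all selected, with A_min = 50 mm² inclusive.  Map assignment uses
standard-space Euclidean distance: candidates are maps whose center lies
strictly within d_max = 25 mm of at least one cluster vertex, and the
closest center wins.  Atlas centers are user-supplied configuration;
the package ships only synthetic atlases for generated meshes, and
real-data use requires the published center coordinates.

## Topography

Preferred numerosities are binned on [1, 5] at width 0.5 (eight bins,
centers 1.25 … 4.75); intervals are half-open [a, b) with the final bin
closed at 5.  Bin area assigns a triangle to the bin of its three
vertices' mean μ̂ (a vertex-area–weighted alternative is not currently
exposed); bin width statistics are the mean and SEM of FWHM over the
bin's vertices.  The within-cluster topography model regresses μ̂ on
powers x^k, y^k, z^k (k = 1…5, no interaction terms) of mean-centered
standard-space coordinates, with per-column scaling inside the solver
for conditioning (predictions are scale-invariant; translation
invariance is exact by mean-centering, rotation invariance is not — the
basis is axis-aligned).  Folds are a seeded uniform partition (10-fold);
cv-r is the Pearson correlation between actual and pooled out-of-fold
predictions, tested with the standard correlation t-test on n − 2
degrees of freedom.

## Group statistics

The mixed model is dv ~ hemisphere + μ:hemisphere with a subject random
intercept (hemisphere-specific slopes of area or FWHM over binned μ),
fitted by REML via statsmodels MixedLM with Wald z/p/CI; noise-free
data, where the mixed likelihood is singular, fall back to the OLS
solution the model degenerates to.  The categorical control GLM uses six
HRF-convolved condition regressors plus confounds and the contrast
(⅕,⅕,⅕,⅕,⅕,−1); group inference is a vertex-wise one-sample t-test with
one-sided p-values in both directions, uncorrected by default.
Bayesian correlations use the exact sampling density of Pearson's r
given ρ (hypergeometric form) — appropriate at n ≈ 12 where Fisher's z
is not — integrated numerically over a uniform prior on [−1, 1];
BF₁₀ is the prior marginal likelihood over the likelihood at ρ = 0.

## Synthetic data

The generator reproduces the study conditions: 8 runs × 145 volumes at
TR 2.1 s under the blocked cycle above.  Maps are rectangular patches on
a regular triangulated sheet with a μ gradient along one axis —
log-spaced by default, so equal cortical extent covers equal
log-numerosity steps and per-bin area falls roughly as 1/μ — and FWHM
increasing linearly with μ (default ω = 1 + 0.8 μ); tuned vertices get
positive scaling (default β = 1.5 % signal change), all others are null.
Signals are generated as y = β·s + ε with i.i.d. Gaussian noise (AR(1)
optional) and, unless percent units are requested, wrapped around a
baseline as β₀·(1 + y/100) so the percent-signal-change step is
exercised.  Confound tables (random-walk motion, noisy tissue means) are
generated for pipeline plumbing but contribute nothing to the signals by
default, keeping analytic checks exact.

Noise is calibrated per vertex so the fit on the split-half training
average attains a target R² in expectation: per-run σ² =
(n_runs/2)·Var(β·s)·(1−R²)/R².  Anchoring the calibration to the series
tuning is actually trained on makes the expected cross-validated R²
land near the same target; the default target 0.3 puts tuned vertices
comfortably but not trivially above the 0.1625 selection threshold
(observed sensitivity ≈ 80 %, specificity ≈ 100 % — computed by the test
suite and acceptance script, not assumed).

What the simulations do not emulate: spatial noise correlations,
vertex-to-vertex HRF variability, motion artifacts coupled to the
confounds, non-rectangular map geometry, and curvature (meshes are
flat sheets; area computations are exercised under rigid motion in
tests, not under realistic folding).  Passing recovery tests therefore
establishes estimator correctness under the stated generative model,
not performance on real cortical data.

## Problem sizes

Default experiment sizes were chosen to estimate each quantity stably
with single-CPU runtimes of seconds: 1,000 null vertices for
specificity, ~880 tuned vertices for recovery error, 20 replicates of a
~1,000-vertex two-map hemisphere for end-to-end map recovery.

## Known limitations

- Grid resolution bounds estimation accuracy at ±0.025 in μ; no
  gradient-based refinement is attempted (by design).
- The F-test treats n = 145 scans as the effective sample size of the
  run-averaged series, mirroring the analysis convention; averaging
  changes the noise scale but not the test's validity under the null.
- `bayes_correlation` evaluates the posterior on a ρ grid (4001 points);
  Bayes factors for |r| near 1 are reported as large finite values or
  infinity at the degenerate limit.
- The pipeline analyzes one hemisphere per call; bilateral analyses loop
  and combine tables.
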