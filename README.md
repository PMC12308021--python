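# numtune

Numerosity population receptive field (pRF) analysis on cortical
surfaces: estimate log-Gaussian numerosity tuning per vertex from
blocked-design BOLD time series, select significantly tuned vertices,
and characterize topographic numerosity maps.

## The problem

Neural populations in several human cortical regions are tuned to
numerosity — the number of items in view — and neighboring patches of
cortex prefer neighboring numerosities, forming topographic maps.  With
surface-sampled fMRI from a blocked design (dot arrays of 1–5 dots in
ascending/descending sweeps, alternating with 20-dot baseline blocks),
each vertex's time series can be modeled with a population receptive
field: a tuning curve over numerosity whose parameters are estimated by
forward-modeling the BOLD response.

`numtune` implements this analysis for researchers in numerical
cognition and computational neuroimaging, together with a synthetic-data
generator that plants known maps on a mesh so estimator accuracy,
selection sensitivity/specificity and map recovery can be measured
against ground truth.

## Model

The neuronal response of a vertex to numerosity `x` presented at time
`t` is log-Gaussian,

    z(t) = exp(−½ ((ln x − μ_log) / σ_log)²),   μ_log = ln μ,

with preferred numerosity `μ` and log-space width `σ_log`, reported as
the FWHM in linear numerosity units

    ω = exp(μ_log + √(2 ln 2) σ_log) − exp(μ_log − √(2 ln 2) σ_log)
      = 2 μ sinh(√(2 ln 2) σ_log).

The predicted BOLD signal is `s(t) = z(t) * h(t)` (canonical double-gamma
HRF), linked to the measured, percent-signal-change-standardized and
confound-cleaned signal by `y(t) = β s(t) + β₀ + ε(t)`.  `(μ, σ_log)` are
estimated by exhaustive grid search (μ: 0.8–5.2 step 0.05; σ_log:
0.05–3.0 step 0.05; 5340 combinations) maximizing the Gaussian
log-likelihood, equivalent to least squares.  Out-of-sample fit (cvR²)
comes from split-half cross-validation over odd/even runs; significance
from an F-test on cvR² with p = 2 free parameters (β₀, β), Bonferroni-
corrected over the vertices of a hemisphere (for 100,000 vertices at
α = 0.05 this gives the threshold R² = 0.1625).  Selected vertices
(β > 0, 1 ≤ μ ≤ 5, cvR² above threshold) are clustered on the mesh,
clusters below 50 mm² are dropped, survivors are assigned to the six
canonical numerosity maps (NTO, NPO, NPC1–3, NF) by proximity to atlas
centers, and topography is quantified by binned area/width summaries and
a cross-validated coordinate-polynomial model of μ.

## Worked example

Simulate a synthetic hemisphere with two planted maps and analyze it:

```sh
numtune simulate --seed 5 -o ds/
numtune fit --events ds/events.tsv --signals ds/ --confounds ds/ -o ds/fits.tsv
```

which prints

```
Numerosity pRF grid-search fit
======================================
vertices analyzed     1008 / 1008
grid combinations     5340
tuning family         log-Gaussian
median cvR2           0.0066
max cvR2              0.3943
mu range (fitted)     [0.80, 5.20]
```

The median cvR² is near zero because most vertices are null; the tuned
vertices reach cvR² ≈ 0.4.  Selecting, clustering and summarizing:

```sh
numtune select --fits ds/fits.tsv --n-vertices 100000 -o ds/sel.json
numtune cluster --fits ds/fits.tsv --vertices ds/vertices.tsv \
    --triangles ds/triangles.tsv --atlas ds/atlas.json -o ds/clusters.tsv
```

yields two clusters matching the planted maps:

```
cluster_id  hemi  n_vertices  area_mm2  assigned_map  mu_min  mu_max
0           L     103         298.0     NPC1          1.00    4.90
1           L     103         296.0     NPO           1.05    5.00
```

Each planted map is recovered as a >50 mm² cluster with the correct
atlas label and represented numerosities spanning the planted 1–5
gradient.  The same analysis is available from Python via
`NumerosityPRF(runs, timeline).fit()`, which returns a results object
with the per-vertex estimates table, `summary()`, selection and
plotting helpers (see `numtune.pipeline.run_pipeline` for the one-call
version).

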