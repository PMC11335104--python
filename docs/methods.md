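# Methods

This note documents the models implemented in `enmoccu`, the choices made
where the methodology left room, and what the synthetic test bed does and
does not establish.

## Maximum-entropy niche model

The ENM core estimates a Gibbs distribution over background cells.  With
feature vector `f(x)` (layers min–max rescaled to [0, 1] over the
background; linear features are the rescaled values, quadratic features
their squares; values outside the background range clamp to [0, 1] during
projection), the fit minimizes

```
J(λ) = −(1/m) Σ_pres λ·f(x) + log Σ_bg exp(λ·f(x)) + Σ_j β_j |λ_j| .
```

Per-feature penalties follow the Phillips–Dudík default scheme:
`β_j = r · β_class(m) · sqrt(var_j / m)`, where `r` is the user's
regularization multiplier (candidate grid 0.1–5, conventional default 1),
`β_class(m)` interpolates the published per-class tables by presence count
`m` (clamped at the tabulated ends), and `var_j` is the feature variance
over the presence sample (ddof = 0, so duplicating the presence list leaves
the pure loss invariant).  Only linear and quadratic classes are
implemented — the optimizer then faces a smooth convex objective plus an L1
term, solved by FISTA with backtracking.  Convergence is declared when the
KKT residual (the smooth gradient shifted by the active L1 subgradient)
falls below 1e−6 in sup-norm; the proximal step yields exact zeros, so the
nonzero-weight count K used by AICc is well defined, and K is non-increasing
in the regularization multiplier.

Outputs: *raw* (the Gibbs probabilities, summing to 1 over the training
background) and *cloglog* `1 − exp(−e^H · raw)` with `H` the entropy of the
raw distribution.  Consensus and thresholding operate on cloglog; AICc uses
raw renormalized over all background cells with K = nonzero weights
(Warren–Seifert convention) and the small-sample correction
`2K(K+1)/(n−K−1)`.

The background is every valid cell inside the accessible area M, or a
seeded uniform sample of 10,000 when there are more.  Presence features are
read from the cell containing each record (cell-centre snap).

## Candidate evaluation and selection

* **Omission rate**: the threshold is the E-percentile (default E = 5) of
  the *training*-presence suitabilities (linear-interpolation percentile);
  omission is the percentage of test presences below it.
* **Partial ROC**: the ROC plots sensitivity against the fraction of
  background predicted present across thresholds spanning the background
  suitability distribution.  Both the model's and the diagonal's areas are
  integrated only over the high-sensitivity region (sensitivity ≥ 1 − E);
  because the curve is monotone, the region boundary is found by
  interpolating the single crossing rather than selecting discrete rows —
  this removes a selection bias that otherwise pushes the null p-value well
  below 0.5.  Bootstrap: 500 iterations resampling 50% of test presences
  with replacement (common kuenm practice; the counts are configurable);
  p = share of bootstrap AUC ratios ≤ 1.
* **Selection**: omission < 5%, mean AUC ratio > 1, p < 0.05, then
  ΔAICc ≤ 2 computed *within* the surviving set.  All four cuts are
  configurable.  The pipeline stage (not the library function) adds a
  recorded fallback ladder — drop the omission cap, then AICc support only —
  because with 20–30 test presences the omission criterion is knife-edge and
  can exclude every candidate at once on unlucky splits.
* **Consensus**: cell-wise median of the selected cloglog maps (nodata if
  any input is nodata); binarization threshold = mean over selected models
  of each model's 10th-percentile training-presence suitability; ties at
  the threshold count as presence.

## Single-season occupancy model

Logit-linear occupancy and detection with the standard marginal site
likelihood; unconducted surveys contribute nothing (their covariate values
are irrelevant and are zeroed defensively).  Covariates are standardized to
mean 0, sd 1 before fitting, with the (mean, sd) record kept for
natural-unit prediction.  The MLE uses BFGS from zero-initialized
coefficients plus four seeded N(0, 0.5) jittered restarts (small-sample
occupancy likelihoods can be multimodal); fits with any coefficient beyond
±15 on the logit scale are flagged as boundary/separation cases, as are
datasets with no detections at all (ψ and p not separately identifiable).
AICc uses n = number of sites, the common convention for occupancy designs
(consistent with the published tables' K accounting, e.g. p(N_obj)ψ(.) has
K = 3).

Model selection is detection-first: all detection candidates are fitted
with constant occupancy, the AICc-best detection structure is fixed, and
the occupancy candidates are then compared.  Candidate lists carry at most
two covariates each; the default lists (20 detection-stage, 67
occupancy-stage) are generated from the study's covariate names and can be
replaced by the user.

**Goodness of fit** is the MacKenzie–Bailey χ² on detection-history
frequencies, with sites grouped into cohorts by missingness pattern; the
statistic sums `(O_h − E_h)²/E_h` over observed histories plus a pooled
term for all unobserved histories (algebraically equal to enumerating every
possible history, which the tests verify).  The parametric bootstrap
simulates from the fitted model respecting the missingness pattern, refits
(single start at the fitted values), and reports
`p = (1 + #{T_s ≥ T_obs}) / (n_ok + 1)`; refit failures are dropped up to a
10% ceiling.  Default 1000 simulations; the calibration check uses 100
meta-replicates × 200 simulations to stay affordable.

Prediction curves use delta-method confidence intervals on the logit scale
(covariance from the inverse numerical Hessian at the MLE), back-transformed
so the limits stay inside (0, 1).

## Integration and areas

The coarse binary niche map masks a fine-resolution (default 0.00025°)
occupancy projection: a fine cell survives iff the coarse cell containing
its centre is presence.  The masked surface is binarized at its own third
quartile, computed with the type-7 (linear interpolation between order
statistics) quantile — the numpy/R default.  Ties at the threshold count as
presence, so a *constant* occupancy surface (an intercept-only best model)
degenerates to "all masked cells pass"; the stage warns when this happens.
When the best model has a single ψ covariate, the natural-unit covariate
value implied by the threshold (the inverse of the prediction curve) is
available as a cross-check.

Cell areas use fixed spherical-degree constants — 111.320 km/deg of
longitude at the equator scaled by cos(latitude), 110.574 km/deg of
latitude — an approximation the tests bound at <1% against an equal-area
projection oracle at low latitudes.

EOO is the convex-hull area in a Lambert azimuthal equal-area projection
centred on the record centroid; AOO counts occupied cells of a 2-km grid
anchored at the projected origin (fixed anchoring for determinism; IUCN
guidance permits shifting the grid to minimize AOO, which is deliberately
not done).

Geodesy throughout is spherical (mean radius 6371.0088 km): haversine
distances for thinning, a centroid-centred azimuthal-equidistant projection
for the 50-km buffers and the accessible-area construction (M = convex hull
of the buffered records ∩ region polygon).

## Synthetic data

The generator emulates the study conditions so the pipeline is testable
offline:

* **Landscapes**: standardized Gaussian random fields (white noise smoothed
  by a Gaussian kernel of width `autocorr_range` cells); one designated
  layer pair is mixed to a target Pearson correlation (default 0.92,
  mimicking ground-level vs atmospheric temperature measurements of the
  same quantity), and the two pipeline variable sets each carry one member
  of that pair plus the shared remaining layers.
* **Occurrences**: cells drawn with probability ∝ a known Gibbs surface
  times `exp(bias_strength × smooth bias field)` — the bias field stands in
  for accessibility bias without needing road data.  Default 164 records,
  thinned at 1 km.
* **Detection histories**: 30 sites × 5 occasions with 5 surveys missing
  uniformly at random (the mechanism behind the study's unconducted surveys
  is unknown; uniform missingness is a stand-in, never leaving a site
  unsurveyed).  Truth coefficients act on the standardized covariate scale:
  occupancy declines with vegetation height (slope −1.5) and detection
  rises with cover-object count (+1.2), the two effects the field study
  identified; site covariates are drawn from plausible natural-unit
  distributions (gamma vegetation heights and depths, Poisson object
  counts).

What passing tests show — and what they do not: the synthetic landscape has
stationary, isotropic covariates, exchangeable train/test presences and a
correctly specified logit-linear occupancy truth.  Real rasters have
non-stationary gradients, records have spatially structured errors, and
occupancy covariate effects need not be logit-linear; calibration and
recovery results here therefore validate the *implementation*, not the
field performance of the workflow.  At the study's 30-site size the
AICc-best occupancy model is sometimes the intercept-only one even with a
real simulated effect — honest small-sample behaviour that the integration
stage then reports as the degenerate all-pass case described above.

## Numerical choices

* Detection probabilities are clipped to [1e−12, 1 − 1e−12] inside the
  likelihood; site likelihoods are floored at 1e−300 before logging.
* Maxent feature variances are floored at 1e−12 in the penalty; constant
  layers are rejected with the layer named.
* Correlation filtering is greedy in input order (keep a layer iff its
  |Spearman ρ| with every already-kept layer is below 0.8), making the
  retained set order-stable and reproducible; the full matrix is returned
  for inspection.
* Thinning is greedy in input order (reproducibility over optimality).
* Quantiles and percentiles are type 7 throughout.
* Problem sizes in the calibration checks (e.g. 25 enumeration datasets,
  200 sign-recovery replicates, 100 × 200 goodness-of-fit bootstrap) are
  the package's chosen defaults balancing statistical resolution against
  runtime.

## Known limitations

* Only l, q, lq feature classes; no hinge/product/threshold features.
* Spherical geodesy and fixed km/degree constants (documented
  approximations; fine at the tens-of-kilometres scale targeted).
* The partial-ROC threshold sweep uses 101 background quantiles; extremely
  discrete suitability surfaces may need a finer sweep.
* The AOO grid anchoring is fixed, so reported AOO can exceed the IUCN
  minimum-over-shifts definition by up to a few cells.
* Raster I/O is single-band ESRI ASCII; no compressed or multi-band
  containers.
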