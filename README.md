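# enmoccu — two-scale species range estimation

`enmoccu` estimates where a species actually lives by combining two models
that operate at different spatio-temporal scales:

1. **A maximum-entropy ecological niche model (ENM)** relates presence-only
   occurrence records to environmental raster layers.  It estimates a Gibbs
   distribution over background cells, `P(x) = exp(λ·f(x)) / Z`, by
   minimizing the L1-penalized log loss

   ```
   J(λ) = −(1/m) Σ_presences λ·f(x) + log Σ_background exp(λ·f(x)) + Σ_j β_j|λ_j|
   ```

   over a candidate grid of regularization multipliers × feature classes
   (linear, quadratic, linear-quadratic) × variable sets.  Candidates are
   scored by omission rate, bootstrap partial-ROC AUC ratio, and AICc;
   survivors are fused by a cell-wise median and binarized at the mean
   10th-percentile training-presence threshold, giving the *potential
   distribution* and its area.

2. **A single-season occupancy model with imperfect detection** explains
   repeated detection/non-detection surveys at a set of sites:
   `logit(ψ_i) = x_i'β`, `logit(p_ij) = w_ij'α`, with the site likelihood
   `ψ_i Π_j p_ij^{y_ij}(1−p_ij)^{1−y_ij} + (1−ψ_i)·1{no detections}`.
   Candidate models (each with at most two covariates) are compared
   detection-first by AICc, and fit is checked with a parametric-bootstrap
   MacKenzie–Bailey χ² test.

The *realized distribution* is then the set of fine-resolution cells
(default 0.00025° ≈ 27 m) that lie inside the binary niche map **and**
whose predicted occupancy exceeds the third quartile (Q3) of the masked
occupancy surface, with latitude-aware area accounting.  IUCN-style EOO
(convex-hull extent) and AOO (occupied 2 × 2 km cells) comparators are
included.

The package is aimed at ecologists and conservation analysts who have
presence records, environmental rasters and a repeat-survey design, and
want a reproducible, scriptable version of this workflow.  Because real
workflows of this kind depend on large external rasters, the package also
ships a first-class synthetic-data module that generates autocorrelated
landscapes, biased occurrence samples and detection histories with known
ground truth, so every stage can be exercised and tested offline.

## Worked example

```python
from pathlib import Path
from enmoccu.pipeline import PipelineConfig, run_all

summary = run_all(PipelineConfig(seed=7), Path("demo_run"))
print(round(summary["potential_area_km2"], 1),
      round(summary["realized_area_km2"], 1))
print(summary["enm"]["selected_models"])
print(round(summary["enm"]["threshold"], 3))
print(summary["occupancy"]["best_model"],
      summary["occupancy"]["naive_occupancy"])
```

On the bundled synthetic study conditions (60 × 60-cell landscape at 0.01°,
164 occurrences thinned at 1 km, a 4 × 3 × 2 candidate grid, 30 sites × 5
occasions with 5 unconducted surveys) this prints:

```
442.6 110.7
['M_0.5_F_l_set_1', 'M_1_F_l_set_1', 'M_2_F_l_set_1', 'M_5_F_l_set_1',
 'M_0.5_F_lq_set_1', 'M_2_F_lq_set_1', 'M_5_F_lq_set_1']
0.166
p(N_obj+T_ground) psi(Veg_H) 0.43333333333333335
```

Reading: the consensus of the seven selected niche-model candidates,
binarized at suitability 0.166, covers 442.6 km² of macro-suitable habitat;
within it, fine-scale occupancy above its own Q3 leaves a realized
distribution of 110.7 km² (realized ⊆ potential always holds).  The best
occupancy model puts vegetation height on the occupancy scale, matching
the simulated truth.  Naïve occupancy — the share of sites with at least
one detection — was 0.43 before correcting for imperfect detection.  Candidate ids follow the
`M_{reg}_F_{features}_set_{k}` naming scheme.  The same pipeline is
available from the shell:

```bash
enmoccu run-all -w demo_run --seed 7
enmoccu occ-select -w demo_run   # writes the AICc model-comparison table
```

Model objects can also be used directly, statsmodels-style:

```python
from enmoccu import OccupancyModel
fit = OccupancyModel(data, psi_covariates=["Veg_H"],
                     p_covariates=["N_obj"]).fit()
print(fit.summary())
curve = fit.predict_curve("Veg_H", np.linspace(0.5, 6.0, 50))
```

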