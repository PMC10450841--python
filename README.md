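# enmshift

Maximum-entropy species distribution modelling with candidate-model
calibration, habitat range-shift analysis, and climatic-novelty (MESS/MoD)
surfaces.

`enmshift` is for ecologists and biogeographers who model where a species
can live from presence-only records and gridded environmental layers, and
who need the *whole* workflow — occurrence cleaning, model tuning, variable
importance, thresholded habitat maps, change/centroid analysis under future
climate scenarios — as reproducible, scriptable, tested code rather than a
chain of GUI tools.

## The model

Given presences x₁..x_m and a background sample b₁..b_N of landscape cells,
the fitted suitability model is the Gibbs distribution P(b) ∝ exp(η·f(b))
maximizing the L1-penalized log likelihood

    J(η) = (1/m) Σ η·f(xᵢ) − log Σ exp(η·f(bⱼ)) − Σⱼ βⱼ|ηⱼ|

where f expands variables into the maxent feature classes (Linear,
Quadratic, Product, Hinge, Threshold) and βⱼ are per-feature penalties
scaled by a global regularization multiplier (RM). Candidate models over a
(feature classes × RM) grid are scored by partial-ROC significance,
omission rates, AUC and sample-size-corrected AIC; the significant,
low-omission candidate with ΔAICc = 0 is selected and refit with replicate
splits. Suitability maps are binarized at the maximum
sensitivity-plus-specificity threshold; binary maps across time slices give
retention/gain/loss areas (spherical cell areas) and great-circle centroid
shifts; MESS/MoD surfaces flag climates outside the calibration envelope.
See `docs/methods.md` for the full account.

A synthetic-world generator (`enmshift.synthworld`) builds smooth,
partially correlated environmental rasters with a known Gaussian niche and
additive "future" climate shifts, so the entire pipeline is testable
offline against ground truth.

## Worked example

```python
from enmshift import synthworld as sw
from enmshift.workflow import PipelineConfig, run_pipeline

cfg = sw.default_config(seed=1)                      # 100x100 world, 5 layers
current, scenarios, niche = sw.make_world(cfg)       # "warm": +3 degC shift
records = sw.sample_presences(current, niche, 150, seed=11)

config = PipelineConfig(
    species="synthetic specialist",
    rm_values=[0.5, 1.0, 2.0],
    fc_combos=["L", "LQ", "Q", "LQH"],
    n_background=2000, replicates=5, proc_boot=200,
    hinge_knots=10, screen=False, seed=1,
)
report = run_pipeline(config, stack=current, scenarios=scenarios,
                      records=records)
print(report.selected_fc, report.selected_rm)
print(report.replicate_metrics["auc_test"].mean())
print(report.contribution.round(1))
print(report.scenario_summaries)
```

Output (abridged):

```
selected: LQ 0.5
mean test AUC: 0.864
temp      40.2
precip    31.0
tcorr     23.8
noise1     3.0
noise2     1.9
scenario  area_km2  shift_km  bearing_deg  gain_km2  loss_km2
 current  39965.11      0.00          NaN       NaN       NaN
    warm  33787.47    128.95        11.66  23170.86  29348.51
```

Reading this: calibration picked linear+quadratic features at RM 0.5; the
replicate-mean held-out AUC is 0.86; the two true niche variables (temp,
precip) carry ~71% of the percent contribution while the pure-noise layers
get ~5%; under +3 °C of warming the suitable range contracts from ~40,000
to ~34,000 km² and its centroid moves 129 km at bearing 11.7° — i.e.
poleward, as the imposed warming on a northward-cooling temperature
gradient demands. The warm-scenario MESS is negative over 64% of cells
(novel climate), most dissimilar variable: temperature.

A CLI wraps the same stages:

```bash
enmshift synthworld --seed 7 --out world/     # fixture world + occurrences
enmshift run --config config.yaml             # full pipeline from YAML
```

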