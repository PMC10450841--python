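# Methods

## Model

`enmshift` fits a presence/background maximum-entropy species distribution
model. Given presence samples x_1..x_m and a background sample b_1..b_N of
landscape cells, the model is the Gibbs distribution over the background

    P(b) ∝ exp(η · f(b))

whose coefficients maximize the L1-penalized objective

    J(η) = (1/m) Σ_presence η·f(x) − log Σ_background exp(η·f(b)) − Σ_j β_j |η_j|.

`f` is the maxent feature expansion of the environmental variables (below),
`β_j` per-feature penalties. The *raw* output `exp(η·f(x) − log Z)` sums to
one over the background sample; the *logistic* output `r/(1+r)` with
`r = e^H · raw(x)` (H the entropy of the fitted distribution) maps
suitability into (0, 1) so that a background cell scores 0.5 under the
uniform model. Presence cells are appended to the background sample by
default (the usual presence/background convention; configurable off).

Assumptions inherited from this model family: occurrences are an unbiased
(after thinning) sample of where the species persists, background cells
characterize available environment, and suitability depends on environment
only — no dispersal limits, no biotic interactions.

## Features and regularization

Raw variables are min-max scaled to `z = (x − min)/(max − min)` → `[0, 1]`
using the background range; features are built on `z`:
linear `z`, quadratic `z²`, product `z_i z_j`, forward/reverse hinges
`max(0, z−k)/(1−k)` and `max(0, k−z)/k` at equally spaced interior knots
(30 per variable by default), and threshold indicators `z > k` (20 knots by
default). Working on the scaled variable makes every feature class invariant
to positive affine transforms of the raw data. Categorical variables (e.g.
land cover) contribute one 0/1 indicator per observed class.

Penalties follow the published default schedule,
`β_j = RM · r_class(m) · max(s_j, 0.001 · s_bg_j)/√m`, with `s_j` the
presence-sample sd of the feature, a background-sd floor, and `r_class`
piecewise-linear in m, clamped at the anchor ends:
L (10,1.0)(30,0.2)(100,0.05); Q (10,1.3)(17,0.8)(30,0.5)(100,0.05);
P (10,2.6)(17,1.6)(30,0.9)(100,0.05); H constant 0.5; T (0,2.0)(100,1.0).
The global regularization multiplier RM scales all β linearly.

## Solver

Cyclic coordinate ascent. Each coordinate takes a proximal-Newton step: with
model mean m̂_j and model variance v_j of feature j under the current Gibbs
distribution, the candidate update is the soft-threshold solution of the
local quadratic model, then halved until the *exact* objective (recomputed
with a log-sum-exp) does not decrease. The objective is therefore monotone,
and the accepted per-coordinate improvements form a non-negative gain ledger
whose total equals the overall objective improvement — that ledger is the
attribution source for percent contribution. Convergence is declared when a
full sweep improves the objective by at most `tol` (default 1e-7) per
coordinate; `max_iter` (default 5000) caps coordinate updates. At the
solution the KKT subgradient conditions of the L1 problem hold: inactive
coefficients have gradients inside the penalty band, active ones sit exactly
on it. On small problems the solution matches a generic bound-constrained
quasi-Newton optimizer of the same objective to well below 1e-6 in objective
value (asserted in the test suite).

Degenerate cases: a feature that is numerically constant under the current
model (variance ≤ 1e-12) is skipped unless its gradient escapes the penalty
band; a constant raw variable yields all-zero features and a warning;
non-finite feature values are rejected.

## Calibration and model selection

Candidates are the Cartesian product of feature-class combinations and
regularization multipliers (defaults: all 31 nonempty subsets of {L,Q,P,H,T}
minus the degenerate product-only and threshold-only singletons → 29
combinations; RM 0.1–4.0 in steps of 0.1 → 40 values → 1160 candidates).
Each candidate is fit on a single seeded 75/25 split (cost control; the
selected model is refit with replicates) and scored with:

- training/test AUC (Mann–Whitney, ties ½) and their difference;
- omission rates OR5/OR10 — fraction of test scores strictly below the
  training threshold that retains the top ⌈(1−q)·n⌉ training points;
- partial ROC restricted to sensitivity ≥ 0.95: 500 bootstrap resamples of
  half the test points, each giving (partial AUC)/(null partial AUC); the
  p-value is the share of ratios ≤ 1;
- AICc from landscape-standardized raw probabilities at presences with
  K = nonzero coefficients, undefined for K ≥ n−1.

Selection filters to partial-ROC p < 0.05 and OR5 ≤ 0.05, then takes the
minimum-AICc candidate (ΔAICc = 0); ties break by lower RM, then shorter,
then lexicographic FC label. If the filter empties the set, selection falls
back to all candidates with defined AICc and warns. "Statistically
significant with omission ≤ 5%" is read as pROC p < α together with the 5%
omission rate; OR10 is reported but not used as a filter.

The final model is refit with `replicates` (default 10) independent
split/background seeds; the reported suitability raster is the per-cell mean
of replicate logistic rasters and metric tables report replicate means.

## Variable importance and screening

Percent contribution distributes the solver's gain ledger over source
variables (product features split 50/50), floors negatives at zero and
normalizes to 100%. Jackknife importance refits with-only-one and
without-one variable models under identical seeds and compares training
gains (gain = mean presence log-raw + log N; 0 for the uniform model). The
iterative screen alternates dropping variables with contribution < 1% and
the lower-contribution member of any pair with |Pearson r| > 0.8 on the
background sample until the set is stable; both thresholds are config keys.

## Thresholds, range change, centroids

The quasi-threshold is μ − σ of suitability at the occurrence cells
(population sd — the n-denominator form, fixed for determinism). The final
binarization threshold maximizes sensitivity (presence scores ≥ t) plus
specificity (background scores < t) over the unique presence scores;
specificity uses background points since no true absences exist. Cells with
suitability ≥ threshold are suitable (ties suitable, so the maximizing score
itself classifies suitable). Thresholds derived under current climate are
reused unchanged for future scenarios.

Change maps classify aligned binary maps per cell into absent (0→0),
retention (1→1), gain (0→1), loss (1→0); by construction retention + loss =
current suitable cells and retention + gain = future suitable cells. Areas
use the spherical closed form A = R²·Δλ·(sin φ_N − sin φ_S) with
R = 6371.0088 km on the geographic grid (no equal-area projection; the
formula is exact on the sphere). Centroids are area-weighted means of
suitable cell centers on 3-D unit vectors, renormalized; shifts are
haversine distances with initial bearing clockwise from north.

## MESS / MoD

The reference envelope stores the environmental values at the species'
occurrence points under current climate. For a scenario value p of variable
i, with F_i the percentage of reference values strictly below p:
F=0 → 100(p−min)/(max−min); 0<F≤50 → 2F; 50<F<100 → 2(100−F);
F=100 → 100(max−p)/(max−min). The F=100 branch is written so that it is
continuous with the interior branches (the widely circulated variant
"100(max−100)/(max−min)" is dimensionally inconsistent and discontinuous;
the continuous form is the original definition). The cell's MESS is the
minimum component; negativity is exactly equivalent to leaving the envelope
of some variable. MoD records the (first, in envelope order, on ties)
minimizing variable. A degenerate envelope (max=min) scores 100 at the
single value and −∞ otherwise, so out-of-envelope still dominates the
minimum. F = 50 falls in the 2F branch; both adjacent branches give 100
there, so the choice is value-neutral.

## Synthetic world

The generator emulates the *shape* of a regional presence-only study:
a 100×100 grid of 0.05° cells at mid-latitudes; five layers — a
temperature-like variable decreasing northward (range ≈ 12–22), a
precipitation-like variable increasing eastward (≈ 800–1200), a nuisance
layer correlated 0.7 with temperature, and two smooth-noise layers; all with
Gaussian-filtered noise (σ = 4–6 cells). The true niche is Gaussian in
temperature and precipitation with optima at mid-range (17 °C, 1000 mm) and
breadths (1.0 °C, 60 mm) modelling a habitat specialist — the regime in
which presence-background models attain high discrimination. 150 presences
are drawn without replacement with probability proportional to true
suitability. Future scenarios add spatially uniform per-variable deltas
(default: +3 °C warming, +1.8 on the correlated layer), which moves the
optimal isotherm poleward.

What the generator does *not* emulate: spatial sampling bias, observation
error, non-Gaussian or interacting niches, spatially structured climate
change, dispersal constraints and landcover change. Passing recovery tests
therefore demonstrate correctness of the machinery under a known truth, not
predictive skill on real data.

A useful closed form for sanity checks: sampling ∝ s with a k-variable
Gaussian niche gives s = exp(−r²/2) with r² ~ χ²_k under the (approximately
uniform) environment measure, so for k = 2, P(s ≥ t) = 1 − t exactly: about
half of presences score s ≥ 0.5 and 95% score s ≥ 0.05.

## Problem sizes and numerical choices

Paper-scale defaults in `PipelineConfig` (10,000 background cells, 5000
iterations, 10 replicates, 75/25 split, RM 0.1–4.0, 29 FC combinations)
reflect the study design this pipeline reproduces. The synthetic
experiments in the test suite and the acceptance script run at desk scale —
100×100 worlds, 150 presences, 2000-cell background, 5 replicates, a small
candidate grid, LQ features for the recovery experiment (the Gaussian truth
is log-quadratic, so LQ is the matched family) — sizes chosen so the whole
suite completes in well under a minute per experiment while leaving the
statistical conclusions unchanged.

Other fixed choices: half-open cell convention [west, east) × [south,
north) with row 0 = north; cell centers as point locations; exact header
equality required for stack alignment; seeded uniform tie-break when
thinning keeps one record per cell; clamping (clipping projection inputs to
the training range) on by default for scenario transfer; ESRI ASCII values
serialized at round-trip precision.

## Known limitations

- Calibration evaluates one split per candidate; no spatial-block CV.
- No bias grids, cloglog output, or sample weights.
- Areas/centroids assume a spherical Earth (no ellipsoid).
- The iterative screen's 1% / 0.8 thresholds are conventions, not fitted.
- GeoTIFF ingestion is not provided; layers arrive as pre-aligned ESRI
  ASCII grids, and reprojection/resampling is out of scope.
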