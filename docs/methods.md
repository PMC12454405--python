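# Methods

This note documents the models, the synthetic data they are exercised on,
the numerical choices, and the limits of what the bundled experiments can
show.

## Synthetic canopy campaign

The simulator emulates a season-long variety trial: `n_plots` (default 30)
plots, each observed at `n_stages` (default 9) acquisition stages, giving
270 plot-stage observations under the defaults.

**Phenology.** Each plot's true LAI trajectory is unimodal
("rise-then-decline"): an asymmetric Gaussian around the acquisition stage
nearest `peak_stage`,

    LAI(t) = baseline + (peak − baseline) · exp(−r(t) · (t − t*)²),

with `r(t) = rise_rate` before the peak stage `t*` and `decline_rate`
after. This form was chosen over logistic-product curves because it
anchors the maximum exactly on the stage grid and guarantees strict
monotonicity on both sides of the peak — properties the downstream tests
rely on. Per-plot parameters are Gaussian draws around population means
(peak 7 ± 1.5 m²/m², peak stage 4 ± 0.8, baseline 1 ± 0.3, rise 0.15 ±
0.05, decline 0.08 ± 0.03 per squared stage; the spread scales with
`phenology_spread`), so plot peaks span roughly 4–10 m²/m² and early/late
stages populate the low LAI range — covering the 1–10 stratification
range.

**Reflectance.** Two-endmember linear mixing with a Beer–Lambert gap
fraction: cover `f = 1 − exp(−k·LAI)` (default `k = 0.5`), observed
reflectance `R_b = f·veg_b + (1−f)·soil_b`. Default endmembers (bands
475/560/668/717/842 nm): soil (0.12, 0.16, 0.22, 0.26, 0.30), vegetation
(0.04, 0.09, 0.04, 0.25, 0.50) — soil brighter in the visible, darker in
the NIR, so greening sends red down and NIR up, and every index saturates
as `f → 1`, reproducing the dense-canopy saturation that motivates
temporal models. Gaussian noise (SD 0.01 per band) is added and the result
clipped to [0,1]; reported LAI carries measurement noise (SD 0.2 m²/m²,
floored at 0).

**What the simulator does not capture.** Per-pixel texture; panicle
emergence and other composition changes beyond the single cover scalar;
band-specific physiological signals — in particular the default
soil/vegetation contrast at 717 nm is nearly zero (0.26 vs 0.25), so the
red-edge indices (NDRE, MTCI, LCI) carry much less information here than
over real canopies, and the importance ranking reflects that (DVI/NIRv
dominate; NDRE ranks mid-field). Passing tests therefore demonstrate that
the machinery behaves as specified under a controlled, saturating mixing
model — not that the learned weights transfer to field data.

## Radiometric calibration (PEL)

Per band, tarp anchors (known reflectances 0.10/0.30/0.50) sorted by
digital number define consecutive linear segments; the map passes exactly
through every anchor. Outside the anchor range the terminal segments are
extended linearly and the output clipped to [0,1]. Non-monotone anchors
warn but fit; duplicate DNs are an error. Calibration cadence (per flight
vs per season) is left to the caller — the fit consumes whatever anchor
file it is given.

## Vegetation indices and selection

The 15-index library uses the canonical published formulas (NDVI, NDRE,
NIRv, EVI2, WDRVI, VARI, DVI, RVI, EVI, OSAVI, MTCI, TVI, GNDVI, LCI, SAVI
with L = 0.5). A `variant="printed"` compatibility mode reproduces
sign-degenerate transcriptions that circulate in parts of the literature
(e.g. NDVI written with "+" in the numerator, which is identically 1); it
exists for provenance comparison only. EVI is the three-band form with the
blue term, distinguishing it from EVI2. Zero denominators yield NaN
markers with a logged count, never exceptions.

Selection ranks the indices by impurity importance from a 500-tree random
forest regression of LAI on all 15 indices (deterministic per seed,
normalized to sum 1) and keeps the top k (default 6; 10 and 15 serve as
ablation arms). With strongly correlated indices, impurity importance
splits credit arbitrarily among near-equivalent features; the ranking is a
screening device, not an attribution.

## Sequences and standardization

One causal window per (plot, stage): the selected-index vectors at stages
`max(0, t−T+1)..t`, left-padded to window length `T` (default: the full
season) with a validity mask. Features are z-scored with
training-partition statistics only; padded steps are held at exactly zero
(the post-standardization mean) so padding is neutral.

## The CLA regressor

Pipeline order is fixed: input matrix → Conv1D (32 filters, kernel 3,
same-padding over time) → ReLU → max pool (size 2, mask pooled by any) →
LSTM (64 units, unidirectional — crop growth is causal) → dropout →
additive attention → dense head (32 ReLU units → dropout → linear output).

Design choices where the architecture was genuinely open:

- **Attention query.** Additive attention needs a query state; in a
  sequence-to-one encoder there is no decoder state, so the query `s` is a
  learned parameter vector (equivalently, `W_α s` is a learned bias inside
  the tanh). Weights are softmax-normalized over unmasked steps; masked
  steps get a −1e30 score surrogate and exactly zero weight.
- **Convolution axis.** 1-D over time with the indices as channels (the
  natural reading for a temporal feature extractor).
- **Mask channel.** The validity mask is appended as an extra input
  channel to all sequence models. Early-season windows are short, and the
  mask tells the network where in the season the window sits —
  phenological position is genuinely informative for LAI.
- **Regularization (fixed, not tuned):** dropout 0.3 after LSTM and hidden
  dense layers (inverted dropout, inference deterministic), L2 λ = 0.01 on
  all weight matrices (not additive biases), early stopping with patience
  10 monitoring validation MSE, best-epoch weights restored.
- **Optimization.** MSE + L2 penalty minimized by Adam (lr 1e-3, β =
  0.9/0.999), batch size 16 (small batches give more updates per epoch
  within the fixed patience window at ~180 training sequences), max 300
  epochs. Deterministic given seed: one RNG drives initialization,
  shuffling and dropout.

Baselines: DNN (64-32 hidden units), plain CNN (conv + pool + masked
global mean pool + head) and plain LSTM (last-state head) on the same
engine; SVR (RBF, C=10, ε=0.1), random forest (500 trees), PLSR (≤5
components), XGBoost (300 trees, depth 4, η=0.1) and per-index OLS on the
current-stage (T=1) feature vector. All share the split and the
standardization statistics of each replicate.

## Evaluation

Metrics: R² = 1 − SS_res/SS_tot (may be negative), RMSE, MAE, RRMSE =
RMSE/ȳ × 100%. Splits are 2:1 (train = round(2n/3)), random by default
with a seeded permutation; a `by_plot` mode keeps all stages of a plot in
one partition for callers who want to exclude within-plot temporal
leakage. Stratified errors use half-open lower bins [1,3), [3,6) and a
closed top bin [6,10], each bin's RRMSE computed with that bin's own mean;
empty bins are reported absent, observations outside [1,10] counted
separately. All reported model accuracies are validation-partition only.

The default benchmark (`ricelai.benchmark`) replicates the entire study
per seed — simulate, indices, rank, select, split, train, score — so
seed-averaged comparisons include ranking and split variability, not just
training noise. Five replicates run in under a minute per model family on
one CPU; this problem size (270 samples, ≤300 epochs) was chosen to keep
the experiments small while leaving the comparisons stable.

## Known limitations

- The simulator's single cover scalar makes all bands perfectly coupled in
  the noiseless limit; real canopies decouple pigment, structure and water
  signals across bands.
- The feature-count ablation (6 vs 10 vs 15 indices) shows no benefit from
  more indices and the full set is the worst arm on average, but arm
  differences are fractions of an RRMSE point — within-noise ties between
  adjacent arms are expected under this generator.
- Deep-model determinism is exact only single-threaded on one platform;
  across platforms expect float-level differences.
- Raster plot-mean extraction reads multiband TIFFs with an optional
  user-supplied affine transform (pixel-center-in-polygon membership); it
  does not parse embedded CRS metadata.
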