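# ricelai

Full-season estimation of rice leaf area index (LAI, m²/m²) from
plot-level multispectral canopy reflectance time series, built around a
CNN-LSTM-attention (CLA) sequence regressor.

## The problem

LAI — one-sided leaf area per unit ground area — is the workhorse proxy for
rice growth status and yield forecasting, but direct measurement does not
scale. UAV multispectral cameras (five bands: blue 475, green 560, red 668,
red edge 717, NIR 842 nm) make frequent plot-level reflectance observation
cheap; the obstacle is the retrieval model. Single vegetation-index (VI)
regressions fail at both ends of the season: at sparse canopy the soil
background dominates the signal, and at dense canopy the indices saturate —
red reflectance stops responding to additional leaf layers while NIR stays
high. Because a plot's spectral *history* constrains where it sits on its
growth curve, a temporal model can recover what a single snapshot cannot.

## The model

For each plot × acquisition stage, the package assembles a causal window of
the top-k vegetation indices (selected by random-forest importance) over
the stages up to the current one, and regresses the current LAI through:

1. **Conv1D + max pooling** over time — local temporal feature extraction,
2. **LSTM** — directed (past → present) temporal dependency modeling,
3. **additive attention** — per-step scores
   `e_i = v_α' tanh(U_α h_i + W_α s)` with a learned query `s`,
   softmax-normalized into weights `α_i` that form the context vector
   `h* = Σ_i α_i h_i` (a convex combination of the LSTM states),
4. **dense head** — maps `h*` to the scalar LAI prediction.

Overfitting safeguards are fixed by design: dropout 0.3 after the LSTM and
each hidden dense layer, L2 weight regularization (λ = 0.01), and early
stopping with patience 10 on validation loss. The network is implemented in
NumPy with hand-written backpropagation and Adam; gradient correctness is
verified against finite differences in the test suite.

Accuracy is reported as R², RMSE, MAE and RRMSE = RMSE/ȳ × 100%, overall
and stratified into low [1,3), medium [3,6) and high [6,10] LAI ranges.
Baselines sharing the same 2:1 train/validation splits: per-index ordinary
least squares, SVR, random forest, PLSR, XGBoost, and plain DNN/CNN/LSTM
networks.

Around the regressor the package provides the rest of the chain: a
synthetic paddy-canopy simulator (two-endmember linear spectral mixing with
Beer–Lambert gap fraction `f = 1 − exp(−k·LAI)`, unimodal per-plot
phenology, 30 plots × 9 stages by default), piecewise empirical-line (PEL)
radiometric calibration anchored at reference tarps of reflectance
0.10/0.30/0.50, a 15-index VI library, raster plot-mean extraction, and a
reproducible pipeline with a thin `ricelai` CLI.

## Worked example

```python
import ricelai
from ricelai.evaluation import SplitSpec, split_train_val

obs = ricelai.generate_dataset(ricelai.SimulationConfig(seed=1))   # 270 obs
table = ricelai.build_feature_table(obs)                           # 15 VIs
ranking = ricelai.rank_importance(table, seed=1)
data = ricelai.build_sequences(table, ricelai.select_top_k(ranking, 6))

tr, va = split_train_val(len(data), SplitSpec(seed=1))
train, val = data.subset(tr), data.subset(va)
stats = train.feature_stats()
train, val = train.standardized(stats), val.standardized(stats)

model = ricelai.train_model("cla", train, val, seed=1)
rep = ricelai.compute_metrics(val.y, ricelai.predict(model, val))
print(rep)
```

prints (see `examples/04_train_cla.py`):

```
CLA validation: R2=0.842  RMSE=0.89  MAE=0.64  RRMSE=20.62%  (n=90)
```

i.e. on the held-out third of the synthetic campaign the temporal model
explains 84% of LAI variance with under 21% relative error. The
seed-replicated comparison (`examples/05_compare_models.py`) shows the
characteristic ordering — CLA beats the random forest, which beats the best
single-index linear model — and the stratified errors show why: in the low
LAI range single-index regressions reach ~30–70% relative error (soil
background) while the CLA stays near 17%.

The remaining examples cover the simulator (`01`), PEL calibration (`02`)
and index ranking (`03`); `ricelai --help` lists the equivalent CLI
subcommands (`simulate`, `calibrate`, `indices`, `rank`, `select`, `train`,
`predict`, `evaluate`, `compare`, `run`).

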