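"""Train the CNN-LSTM-attention (CLA) model and inspect what it attends to.

Builds causal per-stage windows of the selected indices, splits 2:1, trains
the CLA regressor, and reports validation accuracy plus the attention
weights of one validation sequence -- the model concentrates weight on the
informative recent stages.
"""

import numpy as np

import ricelai
from ricelai.evaluation import SplitSpec, split_train_val

obs = ricelai.generate_dataset(ricelai.SimulationConfig(seed=1))
table = ricelai.build_feature_table(obs)
ranking = ricelai.rank_importance(table, seed=1)
data = ricelai.build_sequences(table, ricelai.select_top_k(ranking, 6))

tr, va = split_train_val(len(data), SplitSpec(seed=1))
train, val = data.subset(tr), data.subset(va)
stats = train.feature_stats()
train, val = train.standardized(stats), val.standardized(stats)

model = ricelai.train_model("cla", train, val, seed=1)
pred = ricelai.predict(model, val)
rep = ricelai.compute_metrics(val.y, pred)
print(f"CLA validation: R2={rep.r_squared:.3f}  RMSE={rep.rmse:.2f}  "
      f"MAE={rep.mae:.2f}  RRMSE={rep.rrmse:.2f}%  (n={rep.n})")
print(f"stopped at epoch {model.history['stopped_epoch']}, "
      f"best epoch {model.history['best_epoch']}")

alpha = model.model.last_attention_weights[0]
print("\nattention weights over pooled time steps of one sequence:")
print(np.round(alpha, 3))
print("weights are nonnegative and sum to", round(float(alpha.sum()), 6))
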