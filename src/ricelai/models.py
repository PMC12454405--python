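"""LAI regressors: the CNN-LSTM-attention (CLA) model and its baselines.

The CLA pipeline runs in a fixed order: (1) the time series of selected
vegetation-index vectors is laid out as a T x F matrix; (2) a same-padded
1-D convolution over time plus max pooling extracts local temporal features
and halves the sequence; (3) an LSTM models temporal dependencies over the
pooled sequence; (4) additive attention with a learned query turns the LSTM
hidden states into a context vector that emphasizes the informative growth
stages; (5) a fully connected head maps the context vector to the scalar
LAI prediction.  Overfitting safeguards are fixed by design: dropout 0.3
after the LSTM and after each hidden dense layer, L2 weight regularization
with lambda 0.01, and early stopping with a patience of 10 epochs on the
validation loss.

Baselines: a two-hidden-layer DNN, a plain CNN (steps 1-2 + global
pooling), a plain LSTM (last-state head) -- all on the same engine -- and
SVR, random forest, PLSR, XGBoost and per-index ordinary least squares on
the current-stage feature vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import RandomForestRegressor
from sklearn.svm import SVR
from xgboost import XGBRegressor

from .features import SequenceDataset
from .nn import (
    AdditiveAttention,
    Conv1D,
    Dense,
    Dropout,
    LSTM,
    MaxPool1D,
    SequenceRegressor,
)

__all__ = [
    "CLAConfig",
    "TrainedModel",
    "MODEL_KINDS",
    "DEEP_KINDS",
    "train_model",
    "predict",
    "fit_linear_vi",
    "CLANet",
]

DEEP_KINDS = ("cla", "dnn", "cnn", "lstm")
MODEL_KINDS = DEEP_KINDS + ("svr", "rfr", "plsr", "xgb", "linear_vi")


@dataclass(frozen=True)
class CLAConfig:
    """Architecture and training hyperparameters.

    The regularization triplet (dropout 0.3, L2 lambda 0.01, patience 10)
    is the method's fixed design; the remaining sizes are modest-capacity
    defaults for a few hundred training sequences.
    """

    conv_filters: int = 32
    conv_kernel: int = 3
    pool_size: int = 2
    lstm_units: int = 64
    attention_dim: int = 32
    head_units: int = 32
    dropout_rate: float = 0.3
    l2_lambda: float = 0.01
    early_stop_patience: int = 10
    max_epochs: int = 300
    batch_size: int = 16
    learning_rate: float = 1e-3
    seed: int = 0

    def validate(self) -> None:
        for name in ("conv_filters", "conv_kernel", "pool_size", "lstm_units",
                     "attention_dim", "head_units", "max_epochs", "batch_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.l2_lambda < 0 or self.learning_rate <= 0:
            raise ValueError("invalid regularization or learning rate")


class _Head:
    """Dense(units)+ReLU -> dropout -> Dense(1); shared by all deep models."""

    def __init__(self, rng, n_in: int, units: int, dropout: float) -> None:
        self.fc1 = Dense(rng, n_in, units)
        self.drop = Dropout(dropout)
        self.fc2 = Dense(rng, units, 1)
        self.layers = [self.fc1, self.drop, self.fc2]

    def forward(self, x, rng):
        a = self.fc1.forward(x)
        self._relu_mask = a > 0
        a = a * self._relu_mask
        a = self.drop.forward(a, rng)
        return self.fc2.forward(a)[:, 0]

    def backward(self, dpred):
        da = self.fc2.backward(dpred[:, None])
        da = self.drop.backward(da)
        da = da * self._relu_mask
        return self.fc1.backward(da)


def _append_mask_channel(X: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Input matrix step of the sequence models: T x F feature window plus
    the validity mask as one extra channel, so the network can locate the
    window within the season (phenological position is informative)."""
    return np.concatenate([X, mask[:, :, None].astype(float)], axis=2)


class CLANet(SequenceRegressor):
    """Conv1D -> ReLU -> MaxPool -> LSTM -> dropout -> attention -> head."""

    def __init__(self, n_features: int, config: CLAConfig) -> None:
        rng = np.random.default_rng(config.seed)
        c = config
        self.conv = Conv1D(rng, n_features + 1, c.conv_filters, c.conv_kernel)
        self.pool = MaxPool1D(c.pool_size)
        self.lstm = LSTM(rng, c.conv_filters, c.lstm_units)
        self.drop_lstm = Dropout(c.dropout_rate)
        self.attn = AdditiveAttention(rng, c.lstm_units, c.attention_dim)
        self.head = _Head(rng, c.lstm_units, c.head_units, c.dropout_rate)
        self.layers = [self.conv, self.pool, self.lstm, self.drop_lstm, self.attn,
                       *self.head.layers]

    def _forward(self, X, mask, rng):
        z = self.conv.forward(_append_mask_channel(X, mask))
        self._relu_mask = z > 0
        z = z * self._relu_mask
        z = self.pool.forward(z)
        pmask = self.pool.pool_mask(mask)
        h = self.lstm.forward(z)
        h = self.drop_lstm.forward(h, rng)
        ctx = self.attn.forward(h, pmask)
        return self.head.forward(ctx, rng)

    def _backward(self, dpred):
        dctx = self.head.backward(dpred)
        dh = self.attn.backward(dctx)
        dh = self.drop_lstm.backward(dh)
        dz = self.lstm.backward(dh)
        dz = self.pool.backward(dz)
        dz = dz * self._relu_mask
        self.conv.backward(dz)

    @property
    def last_attention_weights(self) -> np.ndarray | None:
        return self.attn.last_weights


class CNNNet(SequenceRegressor):
    """Conv1D -> ReLU -> MaxPool -> masked global mean pool -> head."""

    def __init__(self, n_features: int, config: CLAConfig) -> None:
        rng = np.random.default_rng(config.seed)
        c = config
        self.conv = Conv1D(rng, n_features + 1, c.conv_filters, c.conv_kernel)
        self.pool = MaxPool1D(c.pool_size)
        self.head = _Head(rng, c.conv_filters, c.head_units, c.dropout_rate)
        self.layers = [self.conv, self.pool, *self.head.layers]

    def _forward(self, X, mask, rng):
        z = self.conv.forward(_append_mask_channel(X, mask))
        self._relu_mask = z > 0
        z = z * self._relu_mask
        z = self.pool.forward(z)
        pmask = self.pool.pool_mask(mask).astype(float)
        self._pmask = pmask
        self._counts = pmask.sum(axis=1, keepdims=True)
        g = (z * pmask[:, :, None]).sum(axis=1) / self._counts
        return self.head.forward(g, rng)

    def _backward(self, dpred):
        dg = self.head.backward(dpred)
        dz = dg[:, None, :] * self._pmask[:, :, None] / self._counts[:, :, None]
        dz = self.pool.backward(dz)
        dz = dz * self._relu_mask
        self.conv.backward(dz)


class LSTMNet(SequenceRegressor):
    """LSTM -> dropout -> final-step hidden state -> head."""

    def __init__(self, n_features: int, config: CLAConfig) -> None:
        rng = np.random.default_rng(config.seed)
        c = config
        self.lstm = LSTM(rng, n_features + 1, c.lstm_units)
        self.drop = Dropout(c.dropout_rate)
        self.head = _Head(rng, c.lstm_units, c.head_units, c.dropout_rate)
        self.layers = [self.lstm, self.drop, *self.head.layers]

    def _forward(self, X, mask, rng):
        h = self.lstm.forward(_append_mask_channel(X, mask))
        h = self.drop.forward(h, rng)
        self._T = h.shape[1]
        return self.head.forward(h[:, -1, :], rng)

    def _backward(self, dpred):
        dlast = self.head.backward(dpred)
        dh = np.zeros((dlast.shape[0], self._T, dlast.shape[1]))
        dh[:, -1, :] = dlast
        dh = self.drop.backward(dh)
        self.lstm.backward(dh)


class DNNNet(SequenceRegressor):
    """Two-hidden-layer perceptron on the current-stage feature vector."""

    def __init__(self, n_features: int, config: CLAConfig,
                 hidden: tuple[int, int] = (64, 32)) -> None:
        rng = np.random.default_rng(config.seed)
        self.fc1 = Dense(rng, n_features, hidden[0])
        self.drop1 = Dropout(config.dropout_rate)
        self.head = _Head(rng, hidden[0], hidden[1], config.dropout_rate)
        self.layers = [self.fc1, self.drop1, *self.head.layers]

    def _forward(self, X, mask, rng):
        x = X[:, -1, :]
        a = self.fc1.forward(x)
        self._relu_mask = a > 0
        a = a * self._relu_mask
        a = self.drop1.forward(a, rng)
        return self.head.forward(a, rng)

    def _backward(self, dpred):
        da = self.head.backward(dpred)
        da = self.drop1.backward(da)
        da = da * self._relu_mask
        self.fc1.backward(da)


_DEEP_BUILDERS = {"cla": CLANet, "cnn": CNNNet, "lstm": LSTMNet, "dnn": DNNNet}


@dataclass
class TrainedModel:
    """A fitted regressor plus everything needed to reproduce predictions."""

    kind: str
    model: object
    feature_names: list[str]
    stats: tuple[np.ndarray, np.ndarray] | None
    config: CLAConfig | None = None
    seed: int = 0
    history: dict = field(default_factory=dict)
    vi_name: str | None = None  # for linear_vi

    def manifest(self) -> dict:
        return {
            "kind": self.kind,
            "feature_names": list(self.feature_names),
            "seed": int(self.seed),
            "config": asdict(self.config) if self.config else None,
            "vi_name": self.vi_name,
            "best_epoch": self.history.get("best_epoch"),
            "stopped_epoch": self.history.get("stopped_epoch"),
        }


def fit_linear_vi(vi_values: np.ndarray, lai: np.ndarray):
    """Ordinary least squares of LAI on a single vegetation index.

    Returns (slope, intercept, fitted values).
    """
    x = np.asarray(vi_values, dtype=float)
    y = np.asarray(lai, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 points")
    if np.ptp(x) == 0:
        raise ValueError("constant predictor")
    A = np.column_stack([x, np.ones_like(x)])
    (slope, intercept), *_ = np.linalg.lstsq(A, y, rcond=None)
    return float(slope), float(intercept), slope * x + intercept


def _check_partitions(train: SequenceDataset, val: SequenceDataset) -> None:
    if len(train) == 0 or len(val) == 0:
        raise ValueError("empty train or validation partition")
    if np.ptp(train.y) == 0:
        raise ValueError("constant training target")
    if not (np.isfinite(train.y).all() and np.isfinite(val.y).all()):
        raise ValueError("non-finite targets")


def train_model(
    kind: str,
    train: SequenceDataset,
    val: SequenceDataset,
    config: CLAConfig | None = None,
    seed: int = 0,
    vi_name: str | None = None,
) -> TrainedModel:
    """Fit one model kind on a train/validation pair of sequence datasets.

    Deep kinds (cla, dnn, cnn, lstm) minimize MSE + L2 with Adam under
    early stopping; classical kinds (svr, rfr, plsr, xgb, linear_vi) fit on
    the current-stage (T=1 view) feature vectors.  Deterministic given
    ``seed`` and a single thread.
    """
    if kind not in MODEL_KINDS:
        raise ValueError(f"unknown model kind {kind!r}; known: {MODEL_KINDS}")
    _check_partitions(train, val)
    config = config or CLAConfig(seed=seed)
    config.validate()
    F = train.X.shape[2]

    if kind in DEEP_KINDS:
        if config.seed != seed:
            config = CLAConfig(**{**asdict(config), "seed": seed})
        net = _DEEP_BUILDERS[kind](F, config)
        history = net.fit(
            train.X, train.mask, train.y, val.X, val.mask, val.y,
            l2=config.l2_lambda, lr=config.learning_rate,
            batch_size=config.batch_size, max_epochs=config.max_epochs,
            patience=config.early_stop_patience, seed=seed,
        )
        return TrainedModel(kind, net, train.feature_names, None,
                            config=config, seed=seed, history=history)

    Xtr = train.current_features
    ytr = train.y
    if kind == "linear_vi":
        if vi_name is None:
            vi_name = train.feature_names[0] if train.feature_names else None
        col = train.feature_names.index(vi_name) if vi_name else 0
        slope, intercept, _ = fit_linear_vi(Xtr[:, col], ytr)
        return TrainedModel(kind, (slope, intercept, col), train.feature_names,
                            None, seed=seed, vi_name=vi_name)
    if kind == "svr":
        est = SVR(kernel="rbf", C=10.0, epsilon=0.1)
    elif kind == "rfr":
        est = RandomForestRegressor(n_estimators=500, random_state=seed, n_jobs=1)
    elif kind == "plsr":
        est = PLSRegression(n_components=min(5, F, len(ytr) - 1))
    elif kind == "xgb":
        est = XGBRegressor(
            n_estimators=300, max_depth=4, learning_rate=0.1,
            random_state=seed, n_jobs=1, verbosity=0,
        )
    est.fit(Xtr, ytr)
    return TrainedModel(kind, est, train.feature_names, None, seed=seed)


def predict(model: TrainedModel, data: SequenceDataset) -> np.ndarray:
    """Predict LAI for every sequence in ``data``."""
    if model.kind in DEEP_KINDS:
        return model.model.predict(data.X, data.mask)
    X = data.current_features
    if model.kind == "linear_vi":
        slope, intercept, col = model.model
        return slope * X[:, col] + intercept
    out = model.model.predict(X)
    return np.asarray(out, dtype=float).reshape(-1)
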