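"""Accuracy metrics, train/validation split, and the model-comparison harness.

Metrics are the four standard agreement measures for crop-parameter
retrieval, computed on measured y, predicted y-hat and the measured mean
y-bar:

    R^2   = 1 - sum (y - y_hat)^2 / sum (y - y_bar)^2
    RMSE  = sqrt( mean (y_hat - y)^2 )
    RRMSE = RMSE / y_bar * 100%
    MAE   = mean |y - y_hat|

R^2 may be negative for a worse-than-mean predictor.  Stratified errors
report per-bin RRMSE over the low [1, 3), medium [3, 6) and high [6, 10]
LAI ranges, each bin using its own measured mean as denominator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import SequenceDataset
from .models import CLAConfig, MODEL_KINDS, TrainedModel, predict, train_model

__all__ = [
    "MetricsReport",
    "StratifiedErrors",
    "SplitSpec",
    "compute_metrics",
    "split_train_val",
    "stratify_errors",
    "compare_models",
    "LAI_BINS",
]

#: (label, lower, upper, upper-closed) for the three LAI strata.
LAI_BINS = (("low", 1.0, 3.0, False), ("medium", 3.0, 6.0, False), ("high", 6.0, 10.0, True))


@dataclass(frozen=True)
class MetricsReport:
    r_squared: float
    rmse: float
    mae: float
    rrmse: float  # percent
    n: int

    def to_dict(self) -> dict:
        return {"r_squared": self.r_squared, "rmse": self.rmse,
                "mae": self.mae, "rrmse": self.rrmse, "n": self.n}


@dataclass(frozen=True)
class StratifiedErrors:
    """Per-bin RRMSE (percent) and counts; bins with no samples are None."""

    bins: dict[str, dict | None]
    n_outside: int

    def to_dict(self) -> dict:
        return {"bins": self.bins, "n_outside": self.n_outside}


@dataclass(frozen=True)
class SplitSpec:
    """2:1 train/validation split, random or grouped by plot."""

    seed: int = 0
    mode: str = "random"  # or "by_plot"

    def validate(self) -> None:
        if self.mode not in ("random", "by_plot"):
            raise ValueError("mode must be 'random' or 'by_plot'")


def compute_metrics(measured, predicted) -> MetricsReport:
    """Evaluate R^2, RMSE, MAE and RRMSE of predictions against measurements."""
    y = np.asarray(measured, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError("measured and predicted must have equal length")
    if y.size < 2:
        raise ValueError("need at least 2 samples")
    ybar = y.mean()
    if ybar == 0:
        raise ValueError("mean of measured values is zero; RRMSE undefined")
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - ybar) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else -np.inf)
    rmse = float(np.sqrt(np.mean((yhat - y) ** 2)))
    mae = float(np.mean(np.abs(y - yhat)))
    rrmse = rmse / ybar * 100.0
    return MetricsReport(r_squared=float(r2), rmse=rmse, mae=mae,
                         rrmse=float(rrmse), n=int(y.size))


def split_train_val(n_or_ids, spec: SplitSpec, plot_ids: list | None = None):
    """Partition sample indices 2:1 into train and validation.

    ``n_or_ids`` is the sample count (or a sequence whose length is used).
    The train partition holds round(2n/3) samples.  In ``by_plot`` mode all
    samples of one plot land in the same partition (``plot_ids`` required,
    one per sample); sizes then match the ratio as closely as whole plots
    allow.  Reproducible given ``spec.seed``.
    """
    spec.validate()
    n = n_or_ids if isinstance(n_or_ids, (int, np.integer)) else len(n_or_ids)
    if n < 3:
        raise ValueError("need at least 3 samples to split 2:1")
    rng = np.random.default_rng(spec.seed)
    n_train = int(round(2 * n / 3))
    if spec.mode == "random":
        perm = rng.permutation(n)
        return np.sort(perm[:n_train]), np.sort(perm[n_train:])
    if plot_ids is None:
        raise ValueError("by_plot mode requires plot_ids")
    plot_ids = np.asarray(plot_ids)
    plots = np.array(sorted(set(plot_ids.tolist())))
    perm_plots = rng.permutation(len(plots))
    train_idx: list[int] = []
    taken = 0
    train_plots = set()
    for pi in perm_plots:
        if taken >= n_train:
            break
        train_plots.add(plots[pi])
        taken += int((plot_ids == plots[pi]).sum())
    is_train = np.isin(plot_ids, list(train_plots))
    return np.flatnonzero(is_train), np.flatnonzero(~is_train)


def stratify_errors(measured, predicted) -> StratifiedErrors:
    """Per-LAI-range RRMSE for the low/medium/high strata.

    Each bin's RRMSE uses the bin's own measured mean; empty bins are
    reported as absent (None).  Observations with measured LAI outside
    [1, 10] are counted separately and excluded from the bins.
    """
    y = np.asarray(measured, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError("measured and predicted must have equal length")
    out: dict[str, dict | None] = {}
    inside = np.zeros(len(y), dtype=bool)
    for label, lo, hi, closed in LAI_BINS:
        sel = (y >= lo) & ((y <= hi) if closed else (y < hi))
        inside |= sel
        if not sel.any():
            out[label] = None
            continue
        yb, yhb = y[sel], yhat[sel]
        rmse = float(np.sqrt(np.mean((yhb - yb) ** 2)))
        out[label] = {"rrmse": rmse / yb.mean() * 100.0, "rmse": rmse, "n": int(sel.sum())}
    return StratifiedErrors(bins=out, n_outside=int((~inside).sum()))


def _seed_offset(seed: int, tag: str) -> int:
    # stable small offset per model kind so kinds get distinct streams
    return (seed * 131 + sum(map(ord, tag))) % (2**31 - 1)


def compare_models(
    data: SequenceDataset,
    kinds: list[str] | tuple[str, ...] = MODEL_KINDS,
    spec: SplitSpec | None = None,
    seeds: list[int] | tuple[int, ...] = (0,),
    config: CLAConfig | None = None,
    vi_name: str | None = None,
) -> pd.DataFrame:
    """Train every model kind on shared splits and report validation accuracy.

    For each seed a single 2:1 split is drawn and shared by all kinds; each
    kind is trained and evaluated on the validation partition, yielding one
    row per (kind, seed) with the metrics and the per-bin RRMSE.  Features
    are z-scored with the training partition's statistics of each split.
    The returned frame also aggregates mean and SD per kind across seeds in
    the attribute ``summary`` (a second DataFrame under ``.attrs``).
    """
    unknown = set(kinds) - set(MODEL_KINDS)
    if unknown:
        raise ValueError(f"unknown model kinds: {sorted(unknown)}")
    spec = spec or SplitSpec()
    rows = []
    for seed in seeds:
        tr_idx, va_idx = split_train_val(
            len(data), SplitSpec(seed=seed, mode=spec.mode), plot_ids=data.plot_ids
        )
        train, val = data.subset(tr_idx), data.subset(va_idx)
        stats = train.feature_stats()
        train, val = train.standardized(stats), val.standardized(stats)
        for kind in kinds:
            model = train_model(kind, train, val, config=config,
                                seed=_seed_offset(seed, kind), vi_name=vi_name)
            yhat = predict(model, val)
            rep = compute_metrics(val.y, yhat)
            strat = stratify_errors(val.y, yhat)
            row = {"kind": kind, "seed": seed, **rep.to_dict()}
            for label, *_ in LAI_BINS:
                b = strat.bins[label]
                row[f"rrmse_{label}"] = b["rrmse"] if b else np.nan
            rows.append(row)
    report = pd.DataFrame(rows)
    summary = (
        report.groupby("kind", sort=False)[["r_squared", "rmse", "mae", "rrmse"]]
        .agg(["mean", "std"])
    )
    report.attrs["summary"] = summary
    return report
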