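"""Vegetation indices, importance ranking, and temporal feature sequences.

The index library covers 15 widely used five-band VIs (blue 475, green 560,
red 668, red edge 717, NIR 842 nm).  Each index exists in two variants:

``canonical``
    The standard published formula (default), e.g. NDVI = (NIR - red) /
    (NIR + red).
``printed``
    A compatibility mode reproducing sign-degenerate transcriptions that
    circulate in parts of the literature (e.g. NDVI written with "+" in the
    numerator, which collapses to the constant 1).  Available only for
    provenance comparisons; never useful for estimation.

Zero denominators yield NaN markers (with a logged count), never exceptions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .bands import BAND_COLUMNS

logger = logging.getLogger(__name__)

__all__ = [
    "VI_NAMES",
    "compute_vi",
    "build_feature_table",
    "rank_importance",
    "select_top_k",
    "build_sequences",
    "standardize_stats",
    "FeatureSequence",
    "SequenceDataset",
    "ImportanceRanking",
]

#: SAVI soil-adjustment constant.
SAVI_L = 0.5


def _safe_div(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    den = np.asarray(den, dtype=float)
    out = np.full(np.broadcast(num, den).shape, np.nan)
    ok = den != 0
    np.divide(np.broadcast_to(num, out.shape), den, out=out, where=ok)
    return out


# Each formula maps (blue, green, red, red_edge, nir) -> index value.
_CANONICAL: dict[str, Callable[..., np.ndarray]] = {
    "NDVI": lambda b, g, r, re, n: _safe_div(n - r, n + r),
    "NDRE": lambda b, g, r, re, n: _safe_div(n - re, n + re),
    "NIRv": lambda b, g, r, re, n: _safe_div(n - r, n + r) * n,
    "EVI2": lambda b, g, r, re, n: 2.5 * _safe_div(n - r, n + 2.4 * r + 1.0),
    "WDRVI": lambda b, g, r, re, n: _safe_div(0.2 * n - r, 0.2 * n + r),
    "VARI": lambda b, g, r, re, n: _safe_div(g - r, g + r - b),
    "DVI": lambda b, g, r, re, n: n - r,
    "RVI": lambda b, g, r, re, n: _safe_div(n, r),
    "EVI": lambda b, g, r, re, n: 2.5 * _safe_div(n - r, n + 6.0 * r - 7.5 * b + 1.0),
    "OSAVI": lambda b, g, r, re, n: 1.16 * _safe_div(n - r, n + r + 0.16),
    "MTCI": lambda b, g, r, re, n: _safe_div(n - re, re - r),
    "TVI": lambda b, g, r, re, n: 0.5 * (120.0 * (n - g) - 200.0 * (r - g)),
    "GNDVI": lambda b, g, r, re, n: _safe_div(n - g, n + g),
    "LCI": lambda b, g, r, re, n: _safe_div(n - re, n + r),
    "SAVI": lambda b, g, r, re, n: (1 + SAVI_L) * _safe_div(n - r, n + r + SAVI_L),
}

# Sign-degenerate transcriptions kept for provenance comparison only.
_PRINTED: dict[str, Callable[..., np.ndarray]] = {
    "NDVI": lambda b, g, r, re, n: _safe_div(n + r, n + r),
    "NDRE": lambda b, g, r, re, n: _safe_div(n + re, n + re),
    "NIRv": lambda b, g, r, re, n: _safe_div(n + r, n + r) * n,
    "EVI2": lambda b, g, r, re, n: 2.5 * _safe_div(n + r, n + 2.4 * r + 1.0),
    "WDRVI": lambda b, g, r, re, n: _safe_div(0.2 * n + r, 0.2 * n + r),
    "VARI": lambda b, g, r, re, n: _safe_div(g + r, g + r),
    "DVI": lambda b, g, r, re, n: n + r,
    "RVI": lambda b, g, r, re, n: _safe_div(n, r),
    "EVI": lambda b, g, r, re, n: 2.5 * _safe_div(n + r, n + 2.4 * r + 1.0),
    "OSAVI": lambda b, g, r, re, n: 1.16 * _safe_div(n + r, n + r + 0.16),
    "MTCI": lambda b, g, r, re, n: _safe_div(n + re, re + r),
    "TVI": lambda b, g, r, re, n: 60.0 * (n + g) + 100.0 * (r + g),
    "GNDVI": lambda b, g, r, re, n: _safe_div(n + g, n + g),
    "LCI": lambda b, g, r, re, n: _safe_div(n + re, n + r),
    "SAVI": lambda b, g, r, re, n: (1 + SAVI_L) * _safe_div(n + r, n + r + SAVI_L),
}

VI_NAMES: tuple[str, ...] = tuple(_CANONICAL)


def compute_vi(
    name: str,
    reflectance: np.ndarray | list[float],
    variant: str = "canonical",
) -> float | np.ndarray:
    """Evaluate one vegetation index.

    ``reflectance`` is a 5-vector (or an N x 5 array) in the canonical band
    order.  Zero denominators produce NaN and are counted in the module log.
    """
    table = {"canonical": _CANONICAL, "printed": _PRINTED}.get(variant)
    if table is None:
        raise ValueError(f"unknown variant {variant!r}")
    if name not in table:
        raise KeyError(f"unknown vegetation index {name!r}; known: {sorted(table)}")
    refl = np.asarray(reflectance, dtype=float)
    scalar = refl.ndim == 1
    refl = np.atleast_2d(refl)
    if refl.shape[-1] != 5:
        raise ValueError("reflectance must have 5 bands in canonical order")
    value = table[name](*(refl[:, i] for i in range(5)))
    n_undef = int(np.isnan(value).sum())
    if n_undef:
        logger.warning("%s: %d undefined value(s) from zero denominators", name, n_undef)
    return float(value[0]) if scalar else value


def build_feature_table(
    observations: pd.DataFrame, variant: str = "canonical"
) -> pd.DataFrame:
    """All 15 indices per observation row.

    Input is the canonical observation table; output carries plot_id,
    stage_index, the 15 VI columns, and the lai target.  Rows with undefined
    (NaN) index values are kept and reported via the module logger.
    """
    if len(observations) == 0:
        raise ValueError("empty observation table")
    refl = observations[list(BAND_COLUMNS)].to_numpy(dtype=float)
    out = observations[["plot_id", "stage_index"]].copy().reset_index(drop=True)
    for name in VI_NAMES:
        out[name] = compute_vi(name, refl, variant=variant)
    if "lai" in observations.columns:
        out["lai"] = observations["lai"].to_numpy(dtype=float)
    n_flagged = int(out[list(VI_NAMES)].isna().any(axis=1).sum())
    if n_flagged:
        logger.warning("%d row(s) contain undefined index values", n_flagged)
    return out


@dataclass(frozen=True)
class ImportanceRanking:
    """Descending (vi_name, score) pairs; scores are non-negative and sum to 1."""

    entries: tuple[tuple[str, float], ...]

    @property
    def names(self) -> list[str]:
        return [name for name, _ in self.entries]

    @property
    def scores(self) -> list[float]:
        return [score for _, score in self.entries]

    def to_dict(self) -> dict[str, float]:
        return dict(self.entries)


def rank_importance(
    table: pd.DataFrame, n_trees: int = 500, seed: int = 0
) -> ImportanceRanking:
    """Rank the indices by random-forest impurity importance for LAI.

    Fits a random-forest regressor of LAI on the 15 indices and returns the
    normalized, descending impurity-based importances.  Deterministic given
    ``seed``.
    """
    if len(table) < 20:
        raise ValueError("need at least 20 rows to rank importances")
    if "lai" not in table.columns:
        raise ValueError("feature table has no lai target column")
    y = table["lai"].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("constant LAI target; importances undefined")
    feats = [n for n in VI_NAMES if n in table.columns]
    X = table[feats].to_numpy(dtype=float)
    ok = ~np.isnan(X).any(axis=1)
    rf = RandomForestRegressor(n_estimators=n_trees, random_state=seed, n_jobs=1)
    rf.fit(X[ok], y[ok])
    imp = np.asarray(rf.feature_importances_, dtype=float)
    imp = imp / imp.sum()
    order = np.argsort(-imp, kind="stable")
    return ImportanceRanking(tuple((feats[i], float(imp[i])) for i in order))


def select_top_k(ranking: ImportanceRanking, k: int = 6) -> list[str]:
    """First ``k`` index names of the ranking (default: the top six)."""
    if not 1 <= k <= len(ranking.entries):
        raise ValueError(f"k must be in [1, {len(ranking.entries)}]")
    return ranking.names[:k]


@dataclass(frozen=True)
class FeatureSequence:
    """Causal window of selected-index vectors ending at one observation.

    ``features`` is T x F (left-padded with zeros where ``mask`` is False);
    ``target`` is the LAI at the final, always-unmasked step.
    """

    plot_id: str
    stage_index: int
    features: np.ndarray
    mask: np.ndarray
    target: float


@dataclass
class SequenceDataset:
    """A batch of sequences stacked into arrays for model consumption."""

    X: np.ndarray  # (N, T, F)
    mask: np.ndarray  # (N, T) boolean
    y: np.ndarray  # (N,)
    plot_ids: list[str]
    stage_indices: list[int]
    feature_names: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.y)

    def subset(self, idx) -> "SequenceDataset":
        idx = np.asarray(idx)
        return SequenceDataset(
            X=self.X[idx],
            mask=self.mask[idx],
            y=self.y[idx],
            plot_ids=[self.plot_ids[i] for i in idx],
            stage_indices=[self.stage_indices[i] for i in idx],
            feature_names=list(self.feature_names),
        )

    @property
    def current_features(self) -> np.ndarray:
        """The T=1 view: the feature vector at each sequence's final step."""
        return self.X[:, -1, :]

    def feature_stats(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-feature mean/SD over this dataset's unmasked steps."""
        vals = self.X[self.mask]
        mean = vals.mean(axis=0)
        sd = vals.std(axis=0)
        return mean, np.where(sd == 0, 1.0, sd)

    def standardized(self, stats: tuple[np.ndarray, np.ndarray]) -> "SequenceDataset":
        """Z-scored copy using the supplied (training) mean/SD.

        Masked (padded) steps stay exactly zero so padding is neutral.
        """
        mean, sd = stats
        X = (self.X - mean) / sd
        X[~self.mask] = 0.0
        return SequenceDataset(
            X=X, mask=self.mask.copy(), y=self.y.copy(),
            plot_ids=list(self.plot_ids), stage_indices=list(self.stage_indices),
            feature_names=list(self.feature_names),
        )


def standardize_stats(table: pd.DataFrame, feature_names: list[str]):
    """Per-feature mean/SD from a (training) feature table, for z-scoring."""
    X = table[list(feature_names)].to_numpy(dtype=float)
    mean = np.nanmean(X, axis=0)
    sd = np.nanstd(X, axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return mean, sd


def build_sequences(
    table: pd.DataFrame,
    selected: list[str],
    window: int | None = None,
    stats: tuple[np.ndarray, np.ndarray] | None = None,
) -> SequenceDataset:
    """Assemble one causal sequence per (plot, stage) row.

    For each observation at stage t the window covers stages
    max(0, t-T+1)..t of the same plot, left-padded (mask False) to length T.
    ``stats`` are the training-partition mean/SD used for z-scoring; passing
    None skips standardization (the caller then owns leakage control).
    """
    unknown = [n for n in selected if n not in table.columns]
    if unknown:
        raise KeyError(f"unknown feature name(s): {unknown}")
    n_stages = int(table["stage_index"].max()) + 1
    T = int(window) if window is not None else n_stages
    if T < 1:
        raise ValueError("window must be >= 1")
    if stats is not None:
        mean, sd = np.asarray(stats[0], dtype=float), np.asarray(stats[1], dtype=float)
    else:
        mean, sd = 0.0, 1.0

    F = len(selected)
    seqs: list[FeatureSequence] = []
    for plot_id, grp in table.groupby("plot_id", sort=True):
        grp = grp.sort_values("stage_index")
        stages = grp["stage_index"].to_numpy(dtype=int)
        feats = (grp[list(selected)].to_numpy(dtype=float) - mean) / sd
        lai = grp["lai"].to_numpy(dtype=float)
        for j, t in enumerate(stages):
            lo = max(0, j - T + 1)
            win = feats[lo : j + 1]
            k = len(win)
            X = np.zeros((T, F))
            m = np.zeros(T, dtype=bool)
            X[T - k :] = win
            m[T - k :] = True
            seqs.append(FeatureSequence(str(plot_id), int(t), X, m, float(lai[j])))
    return SequenceDataset(
        X=np.stack([s.features for s in seqs]),
        mask=np.stack([s.mask for s in seqs]),
        y=np.array([s.target for s in seqs]),
        plot_ids=[s.plot_id for s in seqs],
        stage_indices=[s.stage_index for s in seqs],
        feature_names=list(selected),
    )
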