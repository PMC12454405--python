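"""Radiometric calibration: piecewise empirical line (PEL) from tarp anchors.

Raw sensor digital numbers (DNs) carry no physical unit.  Reference tarps of
known reflectance imaged in the same scene anchor a per-band piecewise
linear map DN -> reflectance: consecutive anchors (sorted by DN) define
linear segments, the map passes exactly through every anchor, and outside
the anchor range the terminal segments are extended linearly before
clipping the output to [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["TarpAnchor", "CalibrationModel", "fit_pel", "apply_pel", "read_anchors"]


@dataclass(frozen=True)
class TarpAnchor:
    """One calibration tarp seen in one band: raw DN and known reflectance."""

    band_id: str
    digital_number: float
    reflectance: float

    def validate(self) -> None:
        if self.digital_number < 0:
            raise ValueError("digital_number must be non-negative")
        if not 0.0 <= self.reflectance <= 1.0:
            raise ValueError("reflectance must lie in [0, 1]")


@dataclass(frozen=True)
class CalibrationModel:
    """Fitted per-band piecewise linear DN -> reflectance maps.

    For each band the anchors are stored sorted by DN together with the
    slope/intercept of every segment between consecutive anchors.
    """

    bands: dict[str, dict[str, np.ndarray]]

    def band_ids(self) -> list[str]:
        return list(self.bands)


def fit_pel(anchors: list[TarpAnchor] | pd.DataFrame) -> CalibrationModel:
    """Fit the piecewise empirical line per band.

    Requires at least two anchors with distinct DNs per band.  Anchors whose
    reflectance is not monotone in DN trigger a warning (the segment-wise
    fit still proceeds); duplicate DNs within a band are an error.
    """
    if isinstance(anchors, pd.DataFrame):
        anchors = [
            TarpAnchor(str(r.band_id), float(r.digital_number), float(r.reflectance))
            for r in anchors.itertuples(index=False)
        ]
    by_band: dict[str, list[TarpAnchor]] = {}
    for a in anchors:
        a.validate()
        by_band.setdefault(a.band_id, []).append(a)
    if not by_band:
        raise ValueError("no anchors supplied")

    fitted: dict[str, dict[str, np.ndarray]] = {}
    for band_id, band_anchors in by_band.items():
        if len(band_anchors) < 2:
            raise ValueError(f"band {band_id!r}: need at least 2 anchors, got {len(band_anchors)}")
        order = sorted(band_anchors, key=lambda a: a.digital_number)
        dn = np.array([a.digital_number for a in order], dtype=float)
        refl = np.array([a.reflectance for a in order], dtype=float)
        if np.any(np.diff(dn) == 0):
            raise ValueError(f"band {band_id!r}: duplicate digital numbers among anchors")
        if np.any(np.diff(refl) < 0):
            warnings.warn(
                f"band {band_id!r}: anchor reflectance is not monotone in DN; "
                "fitting segments anyway",
                stacklevel=2,
            )
        slope = np.diff(refl) / np.diff(dn)
        intercept = refl[:-1] - slope * dn[:-1]
        fitted[band_id] = {"dn": dn, "reflectance": refl, "slope": slope, "intercept": intercept}
    return CalibrationModel(bands=fitted)


def apply_pel(
    model: CalibrationModel, dn: float | np.ndarray, band_id: str
) -> float | np.ndarray:
    """Convert DN(s) to reflectance with the fitted map for ``band_id``.

    Piecewise linear between anchors; outside the anchor range the terminal
    segment is extrapolated, then the result is clipped to [0, 1].
    """
    if band_id not in model.bands:
        raise KeyError(f"no calibration fitted for band {band_id!r}")
    b = model.bands[band_id]
    dn_arr = np.asarray(dn, dtype=float)
    # Segment index for each DN; terminal segments handle extrapolation.
    seg = np.clip(np.searchsorted(b["dn"], dn_arr, side="right") - 1, 0, len(b["slope"]) - 1)
    refl = b["slope"][seg] * dn_arr + b["intercept"][seg]
    refl = np.clip(refl, 0.0, 1.0)
    return float(refl) if np.isscalar(dn) or dn_arr.ndim == 0 else refl


def read_anchors(path) -> list[TarpAnchor]:
    """Read tarp anchors from a CSV with header band_id, digital_number, reflectance."""
    df = pd.read_csv(path)
    required = {"band_id", "digital_number", "reflectance"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"anchor file missing columns: {sorted(missing)}")
    return [
        TarpAnchor(str(r.band_id), float(r.digital_number), float(r.reflectance))
        for r in df.itertuples(index=False)
    ]
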