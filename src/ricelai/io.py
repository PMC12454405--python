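"""Readers and writers for the tabular and raster formats the pipeline touches.

Tables are plain CSV with fixed headers (see ``OBSERVATION_COLUMNS``).
Rasters are multiband TIFFs read with tifffile, with band order matching
the canonical five-band layout; plot polygons come from GeoJSON and an
optional six-parameter affine transform maps pixel centers into the polygon
coordinate system (identity by default, i.e. pixel coordinates).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import Point, shape

from .bands import BAND_COLUMNS, N_BANDS
from .simulate import OBSERVATION_COLUMNS

logger = logging.getLogger(__name__)

__all__ = [
    "read_observations",
    "write_observations",
    "PlotGeometry",
    "read_plot_geometries",
    "extract_plot_means",
]


def read_observations(path) -> pd.DataFrame:
    """Read and validate a canonical observation table.

    Requires the canonical header; rejects non-numeric or out-of-range
    reflectance and negative LAI, reporting offending row indices.
    """
    df = pd.read_csv(path)
    required = [c for c in OBSERVATION_COLUMNS if c != "date_label"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"observation table missing columns: {missing}")
    bad_rows: list[int] = []
    for col in (*BAND_COLUMNS, "lai"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna()
        if col != "lai":
            bad |= (vals < 0) | (vals > 1)
        else:
            bad |= vals < 0
        bad_rows.extend(df.index[bad].tolist())
        df[col] = vals
    if bad_rows:
        raise ValueError(
            f"invalid reflectance/LAI values at row index(es) {sorted(set(bad_rows))}"
        )
    dup = df.duplicated(subset=["plot_id", "stage_index"])
    if dup.any():
        raise ValueError(
            f"duplicate (plot_id, stage_index) at row index(es) {df.index[dup].tolist()}"
        )
    return df


def write_observations(df: pd.DataFrame, path) -> None:
    """Write an observation table with the canonical column order first."""
    cols = [c for c in OBSERVATION_COLUMNS if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    df[cols].to_csv(path, index=False)


@dataclass(frozen=True)
class PlotGeometry:
    """A plot polygon in the raster's coordinate system."""

    plot_id: str
    polygon: object  # shapely geometry

    def validate(self) -> None:
        if self.polygon.is_empty or self.polygon.area <= 0:
            raise ValueError(f"plot {self.plot_id!r}: degenerate polygon")


def read_plot_geometries(path) -> list[PlotGeometry]:
    """Read plot polygons from a GeoJSON FeatureCollection.

    Each feature needs a ``plot_id`` property and a polygon geometry.
    """
    with open(path) as fh:
        gj = json.load(fh)
    geoms = []
    seen = set()
    for feat in gj.get("features", []):
        pid = str(feat.get("properties", {}).get("plot_id", ""))
        if not pid:
            raise ValueError("feature without plot_id property")
        if pid in seen:
            raise ValueError(f"duplicate plot_id {pid!r}")
        seen.add(pid)
        g = PlotGeometry(pid, shape(feat["geometry"]))
        g.validate()
        geoms.append(g)
    return geoms


def extract_plot_means(
    raster_path,
    geometries: list[PlotGeometry],
    transform: tuple[float, ...] | None = None,
) -> pd.DataFrame:
    """Mean reflectance per plot from a multiband TIFF.

    A pixel belongs to a plot when its center falls inside the plot
    polygon.  ``transform`` is an optional affine (a, b, c, d, e, f)
    mapping (col, row) pixel-center coordinates to world coordinates as
    ``x = a*col + b*row + c`` and ``y = d*col + e*row + f``; by default the
    pixel-center coordinates (col + 0.5, row + 0.5) are used directly.
    Plots with no covered pixel are skipped with a warning.
    """
    import tifffile

    arr = np.asarray(tifffile.imread(raster_path), dtype=float)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.shape[0] != N_BANDS and arr.shape[-1] == N_BANDS:
        arr = np.moveaxis(arr, -1, 0)
    if arr.shape[0] != N_BANDS:
        raise ValueError(f"raster must have {N_BANDS} bands in canonical order")
    _, n_rows, n_cols = arr.shape
    cols, rows = np.meshgrid(np.arange(n_cols) + 0.5, np.arange(n_rows) + 0.5)
    if transform is not None:
        a, b, c, d, e, f = transform
        xs = a * cols + b * rows + c
        ys = d * cols + e * rows + f
    else:
        xs, ys = cols, rows

    records = []
    for geom in geometries:
        geom.validate()
        minx, miny, maxx, maxy = geom.polygon.bounds
        cand = (xs >= minx) & (xs <= maxx) & (ys >= miny) & (ys <= maxy)
        idx = np.flatnonzero(cand.ravel())
        inside = [
            i for i in idx if geom.polygon.contains(Point(xs.ravel()[i], ys.ravel()[i]))
        ]
        if not inside:
            warnings.warn(f"plot {geom.plot_id!r}: no pixel centers inside polygon; skipped",
                          stacklevel=2)
            continue
        flat = arr.reshape(N_BANDS, -1)[:, inside]
        rec = {"plot_id": geom.plot_id}
        rec.update({col: float(flat[b].mean()) for b, col in enumerate(BAND_COLUMNS)})
        rec["n_pixels"] = len(inside)
        records.append(rec)
    return pd.DataFrame(records)
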