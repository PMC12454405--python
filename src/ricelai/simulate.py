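"""Synthetic paddy-canopy reflectance time series with known leaf area index.

The generator emulates the statistical structure of a season-long UAV
multispectral campaign over a rice variety trial: a grid of plots, each
observed at a fixed set of acquisition stages, with a unimodal
(rise-then-decline) LAI trajectory per plot and plot-level mean reflectance
in the five camera bands.

Reflectance follows a two-endmember linear mixing model.  The vegetation
cover fraction is the Beer-Lambert gap-fraction complement
``f = 1 - exp(-k * LAI)``, so observed reflectance moves from the bare-soil
spectrum at LAI = 0 toward the closed-canopy vegetation spectrum as the
canopy densifies.  Because ``f`` flattens at high LAI, band reflectance --
and every vegetation index built from it -- saturates at dense canopy,
reproducing the loss of index sensitivity that motivates temporal deep
models for full-season LAI retrieval.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .bands import BAND_COLUMNS, N_BANDS

__all__ = [
    "PhenologyParams",
    "Endmembers",
    "SimulationConfig",
    "simulate_phenology",
    "simulate_reflectance",
    "generate_dataset",
    "OBSERVATION_COLUMNS",
]

#: Canonical observation-table header (see :mod:`ricelai.io`).
OBSERVATION_COLUMNS = ("plot_id", "stage_index", "date_label", *BAND_COLUMNS, "lai")


@dataclass(frozen=True)
class PhenologyParams:
    """Parameters of one plot's unimodal LAI trajectory.

    The curve is an asymmetric Gaussian around the acquisition stage nearest
    ``peak_stage``: LAI rises from near ``baseline_lai`` at rate
    ``rise_rate`` (per squared stage) up to exactly ``peak_lai`` at the peak
    stage, then declines at ``decline_rate``.  This log-concave form
    guarantees a single maximum and strict monotonicity on either side of
    the peak on any stage grid.
    """

    peak_lai: float
    peak_stage: float
    rise_rate: float
    decline_rate: float
    baseline_lai: float = 0.0

    def validate(self) -> None:
        if self.rise_rate <= 0 or self.decline_rate <= 0:
            raise ValueError("rise_rate and decline_rate must be positive")
        if self.baseline_lai < 0:
            raise ValueError("baseline_lai must be non-negative")
        if self.peak_lai <= self.baseline_lai:
            raise ValueError("peak_lai must exceed baseline_lai")


@dataclass(frozen=True)
class Endmembers:
    """Pure-component spectra for the linear mixing model.

    Soil must be brighter than vegetation in the visible bands (475-668 nm)
    and darker in the NIR band (842 nm) -- the contrast that drives the
    characteristic NIR-up / red-down trajectory of a greening canopy.
    """

    soil_reflectance: tuple[float, ...] = (0.12, 0.16, 0.22, 0.26, 0.30)
    vegetation_reflectance: tuple[float, ...] = (0.04, 0.09, 0.04, 0.25, 0.50)
    extinction_k: float = 0.5

    def validate(self) -> None:
        soil = np.asarray(self.soil_reflectance, dtype=float)
        veg = np.asarray(self.vegetation_reflectance, dtype=float)
        if soil.shape != (N_BANDS,) or veg.shape != (N_BANDS,):
            raise ValueError(f"endmember spectra must have {N_BANDS} bands")
        for arr, label in ((soil, "soil"), (veg, "vegetation")):
            if np.any(arr < 0) or np.any(arr > 1):
                raise ValueError(f"{label} reflectance must lie in [0, 1]")
        if not np.all(soil[:3] > veg[:3]):
            raise ValueError("soil must be brighter than vegetation in the visible bands")
        if not soil[4] < veg[4]:
            raise ValueError("soil must be darker than vegetation in the NIR band")
        if self.extinction_k <= 0:
            raise ValueError("extinction_k must be positive")


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters of the synthetic campaign.

    Defaults reproduce the reference design: 30 plots x 9 stages = 270
    observations, small Gaussian reflectance noise (SD 0.01) and an LAI
    measurement error of SD 0.2 m2/m2.
    """

    n_plots: int = 30
    n_stages: int = 9
    phenology_spread: float = 1.0
    reflectance_noise_sd: float = 0.01
    lai_measurement_noise_sd: float = 0.2
    seed: int = 0
    endmembers: Endmembers = field(default_factory=Endmembers)
    # Population means of the per-plot phenology; between-plot SDs are the
    # values below scaled by phenology_spread.
    phenology_mean: PhenologyParams = field(
        default_factory=lambda: PhenologyParams(
            peak_lai=7.0, peak_stage=4.0, rise_rate=0.15, decline_rate=0.08, baseline_lai=1.0
        )
    )
    phenology_sd: PhenologyParams = field(
        default_factory=lambda: PhenologyParams(
            peak_lai=1.5, peak_stage=0.8, rise_rate=0.05, decline_rate=0.03, baseline_lai=0.3
        )
    )

    def validate(self) -> None:
        if self.n_plots < 1 or self.n_stages < 1:
            raise ValueError("n_plots and n_stages must be positive")
        if self.reflectance_noise_sd < 0 or self.lai_measurement_noise_sd < 0:
            raise ValueError("noise standard deviations must be non-negative")
        if self.phenology_spread < 0:
            raise ValueError("phenology_spread must be non-negative")
        self.endmembers.validate()
        self.phenology_mean.validate()


def simulate_phenology(params: PhenologyParams, n_stages: int) -> np.ndarray:
    """Evaluate the unimodal LAI trajectory on ``n_stages`` stages.

    The peak is anchored on the grid: at the integer stage nearest
    ``params.peak_stage`` (clipped into the season) the value is exactly
    ``peak_lai``.  Values are strictly increasing before the peak stage and
    strictly decreasing after it.
    """
    params.validate()
    if n_stages < 2:
        raise ValueError("n_stages must be at least 2")
    t = np.arange(n_stages, dtype=float)
    t_peak = float(np.clip(np.rint(params.peak_stage), 0, n_stages - 1))
    amp = params.peak_lai - params.baseline_lai
    d = t - t_peak
    rate = np.where(d < 0, params.rise_rate, params.decline_rate)
    lai = params.baseline_lai + amp * np.exp(-rate * d**2)
    return lai


def simulate_reflectance(
    lai: float | np.ndarray,
    endmembers: Endmembers | None = None,
    noise_sd: float | np.ndarray = 0.0,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Five-band canopy reflectance for the given LAI.

    Noiseless mixing is ``R_b = f * veg_b + (1 - f) * soil_b`` with cover
    fraction ``f = 1 - exp(-k * LAI)``.  Gaussian noise of per-band standard
    deviation ``noise_sd`` is then added and the result clipped to [0, 1].
    Passing an array of LAI values returns one row per value.
    """
    endmembers = endmembers or Endmembers()
    endmembers.validate()
    lai_arr = np.atleast_1d(np.asarray(lai, dtype=float))
    if np.any(lai_arr < 0):
        raise ValueError("lai must be non-negative")
    soil = np.asarray(endmembers.soil_reflectance, dtype=float)
    veg = np.asarray(endmembers.vegetation_reflectance, dtype=float)
    f = 1.0 - np.exp(-endmembers.extinction_k * lai_arr)
    refl = f[:, None] * veg[None, :] + (1.0 - f)[:, None] * soil[None, :]
    noise_sd_arr = np.broadcast_to(np.asarray(noise_sd, dtype=float), (N_BANDS,))
    if np.any(noise_sd_arr > 0):
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        refl = refl + rng.normal(0.0, 1.0, size=refl.shape) * noise_sd_arr[None, :]
    refl = np.clip(refl, 0.0, 1.0)
    return refl[0] if np.isscalar(lai) or np.asarray(lai).ndim == 0 else refl


def _draw_plot_phenology(config: SimulationConfig, rng: np.random.Generator) -> PhenologyParams:
    mean, sd = config.phenology_mean, config.phenology_sd
    s = config.phenology_spread
    peak = rng.normal(mean.peak_lai, s * sd.peak_lai)
    baseline = max(0.05, rng.normal(mean.baseline_lai, s * sd.baseline_lai))
    return PhenologyParams(
        peak_lai=max(peak, baseline + 0.5),
        peak_stage=rng.normal(mean.peak_stage, s * sd.peak_stage),
        rise_rate=max(1e-3, rng.normal(mean.rise_rate, s * sd.rise_rate)),
        decline_rate=max(1e-3, rng.normal(mean.decline_rate, s * sd.decline_rate)),
        baseline_lai=baseline,
    )


def generate_dataset(config: SimulationConfig | None = None) -> pd.DataFrame:
    """Generate the full synthetic campaign as an observation table.

    Returns a DataFrame with the canonical columns (plot_id, stage_index,
    date_label, five reflectance bands, lai).  ``lai`` is the reported
    (noisy, floored at zero) measurement; the error-free trajectory value is
    kept in ``lai_true`` for oracle checks.  Deterministic given
    ``config.seed``.
    """
    config = config or SimulationConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    rows = []
    for p in range(config.n_plots):
        params = _draw_plot_phenology(config, rng)
        lai_true = simulate_phenology(params, config.n_stages)
        refl = simulate_reflectance(
            lai_true, config.endmembers, config.reflectance_noise_sd, seed=rng
        )
        lai_meas = lai_true + rng.normal(0.0, config.lai_measurement_noise_sd, config.n_stages)
        lai_meas = np.maximum(lai_meas, 0.0)
        for s in range(config.n_stages):
            rows.append(
                {
                    "plot_id": f"P{p + 1:02d}",
                    "stage_index": s,
                    "date_label": f"S{s + 1}",
                    **{col: refl[s, b] for b, col in enumerate(BAND_COLUMNS)},
                    "lai": lai_meas[s],
                    "lai_true": lai_true[s],
                }
            )
    return pd.DataFrame(rows)


def noiseless_config(**overrides) -> SimulationConfig:
    """A convenience config with all noise switched off."""
    base = SimulationConfig(reflectance_noise_sd=0.0, lai_measurement_noise_sd=0.0)
    return replace(base, **overrides) if overrides else base
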