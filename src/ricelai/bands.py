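"""Multispectral band definitions for the five-band RedEdge-class camera.

Band order is fixed everywhere in the package: blue 475 nm, green 560 nm,
red 668 nm, red edge 717 nm, near infrared 842 nm.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class Band:
    """One camera band: center wavelength and bandwidth, both in nm."""

    name: str
    center_nm: int
    width_nm: int


BANDS: tuple[Band, ...] = (
    Band("blue", 475, 32),
    Band("green", 560, 27),
    Band("red", 668, 14),
    Band("red_edge", 717, 12),
    Band("nir", 842, 57),
)

#: Column names used for reflectance in every table the package reads/writes.
BAND_COLUMNS: tuple[str, ...] = tuple(f"b{b.center_nm}" for b in BANDS)

#: Index of each band in the canonical 5-vector, keyed by wavelength and name.
BAND_INDEX: dict[str, int] = {}
for _i, _b in enumerate(BANDS):
    BAND_INDEX[_b.name] = _i
    BAND_INDEX[f"b{_b.center_nm}"] = _i
    BAND_INDEX[str(_b.center_nm)] = _i

N_BANDS = len(BANDS)
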