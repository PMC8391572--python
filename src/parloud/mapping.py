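"""Gridded exposure to partial-loudness and %HA annoyance rasters.

Each receiver cell carries an aircraft and a road LAeq.  Levels are
taken indoors (slightly open windows: -15 dBA aircraft, -15.8 dBA
road), template spectra are built at the indoor levels, and three
loudness values are computed per cell: the aircraft's partial loudness
with the road as background, the road's partial loudness with the
aircraft as background, and the total loudness of the combination.
The long-term annoyance model turns each loudness layer into a %HA
layer, so the maps expose the background-noise (masking) effect:
cells near a loud road show suppressed aircraft annoyance relative to
equally exposed cells in quiet surroundings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .annoyance import AnnoyanceModel, LONG_TERM, indoor_level
from .bands import energetic_sum
from .constants import LoudnessModelConstants, default_constants
from .loudness import diotic_loudness, diotic_partial_loudness

__all__ = [
    "CellLoudness",
    "ExposureGrid",
    "AnnoyanceGrid",
    "cell_loudness",
    "annoyance_surface",
    "exposure_group",
    "exposure_group_number",
    "EXPOSURE_GROUPS",
]

#: Table of exposure groups: (number, label, [lower, upper) in dBA).
EXPOSURE_GROUPS = (
    (1, "less than 50 dBA", -np.inf, 50.0),
    (2, "50-60 dBA", 50.0, 60.0),
    (3, "60-70 dBA", 60.0, 70.0),
    (4, "Over 70 dBA", 70.0, np.inf),
)


@dataclass(frozen=True)
class CellLoudness:
    """Loudness triple of one receiver cell, in sones."""

    aircraft_partial: float
    road_partial: float
    total: float


@dataclass(frozen=True)
class ExposureGrid:
    """Paired outdoor exposure rasters on a square cell grid."""

    origin: tuple
    cell_m: float
    aircraft_dba: np.ndarray
    road_dba: np.ndarray

    def __post_init__(self):
        if self.aircraft_dba.shape != self.road_dba.shape:
            raise ValueError("exposure layers must have the same shape")

    @property
    def shape(self):
        return self.aircraft_dba.shape


@dataclass(frozen=True)
class AnnoyanceGrid:
    """Named loudness and %HA rasters derived from an ExposureGrid."""

    origin: tuple
    cell_m: float
    layers: dict

    def __post_init__(self):
        shapes = {v.shape for v in self.layers.values()}
        if len(shapes) > 1:
            raise ValueError("all layers must share one shape")

    @property
    def shape(self):
        return next(iter(self.layers.values())).shape


_cell_cache: dict = {}


def cell_loudness(
    aircraft_dba: float,
    road_dba: float,
    constants: LoudnessModelConstants | None = None,
    quantize_db: float = 0.01,
) -> CellLoudness:
    """Loudness triple for one cell's outdoor levels.

    Indoor corrections are applied first; indoor levels below 0 dBA
    (or -inf) contribute no excitation.  Results are cached on levels
    quantized to ``quantize_db`` so large grids stay cheap.
    """
    from .synth import template_spectrum

    c = constants or default_constants()

    def _indoor(level, source):
        if not np.isfinite(level):
            return None
        lv = indoor_level(float(level), source)
        return lv if lv > 0.0 else None          # audibility floor

    la = _indoor(aircraft_dba, "aircraft")
    lr = _indoor(road_dba, "road")
    key = (
        None if la is None else round(la / quantize_db),
        None if lr is None else round(lr / quantize_db),
        id(c),
    )
    if key in _cell_cache:
        return _cell_cache[key]
    if la is not None:
        la = key[0] * quantize_db
    if lr is not None:
        lr = key[1] * quantize_db

    spec_a = template_spectrum("aircraft", la) if la is not None else None
    spec_r = template_spectrum("road", lr) if lr is not None else None

    if spec_a is None and spec_r is None:
        out = CellLoudness(0.0, 0.0, 0.0)
    elif spec_r is None:
        n = diotic_loudness(spec_a, c)
        out = CellLoudness(n, 0.0, n)
    elif spec_a is None:
        n = diotic_loudness(spec_r, c)
        out = CellLoudness(0.0, n, n)
    else:
        a_part = diotic_partial_loudness(spec_a, spec_r, c)
        r_part = diotic_partial_loudness(spec_r, spec_a, c)
        total = diotic_loudness(energetic_sum(spec_a, spec_r), c)
        out = CellLoudness(a_part, r_part, total)
    _cell_cache[key] = out
    return out


def annoyance_surface(
    grid: ExposureGrid,
    model: AnnoyanceModel = LONG_TERM,
    constants: LoudnessModelConstants | None = None,
) -> AnnoyanceGrid:
    """Per-cell loudness and %HA layers for both sources and the total.

    Layers: ``loudness_aircraft_partial``, ``loudness_road_partial``,
    ``loudness_total`` (sones) and ``pct_ha_aircraft``,
    ``pct_ha_road``, ``pct_ha_total`` (%, from the long-term model).
    """
    if grid.aircraft_dba is None or grid.road_dba is None:
        raise ValueError("grid must provide both exposure layers")
    c = constants or default_constants()
    shape = grid.shape
    la = np.zeros(shape)
    lr = np.zeros(shape)
    lt = np.zeros(shape)
    it = np.nditer(grid.aircraft_dba, flags=["multi_index"])
    for _ in it:
        ij = it.multi_index
        cell = cell_loudness(grid.aircraft_dba[ij], grid.road_dba[ij], c)
        la[ij], lr[ij], lt[ij] = cell.aircraft_partial, cell.road_partial, cell.total
    layers = {
        "loudness_aircraft_partial": la,
        "loudness_road_partial": lr,
        "loudness_total": lt,
        "pct_ha_aircraft": model(la),
        "pct_ha_road": model(lr),
        "pct_ha_total": model(lt),
    }
    return AnnoyanceGrid(grid.origin, grid.cell_m, layers)


def exposure_group(level_dba: float) -> str:
    """Exposure-group label for an outdoor level (half-open bounds,
    ties to the upper group)."""
    if not np.isfinite(level_dba):
        raise ValueError("exposure level must be finite")
    for _, label, lo, hi in EXPOSURE_GROUPS:
        if lo <= level_dba < hi:
            return label
    raise AssertionError("unreachable")


def exposure_group_number(level_dba: float) -> int:
    """Exposure-group number (1-4) for an outdoor level."""
    label = exposure_group(level_dba)
    for num, lab, *_ in EXPOSURE_GROUPS:
        if lab == label:
            return num
    raise AssertionError("unreachable")
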