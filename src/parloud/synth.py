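"""Synthetic stimuli, jury/survey responses and toy exposure grids.

The package's study conditions are reproduced without any recordings:

* fixed template 1/3-octave spectra with the qualitative character of
  the two sources (aircraft flyovers carry strong high-frequency
  energy; road traffic is broadband with a low-frequency tilt),
* flyover waveforms as shaped noise with a smooth rise-fall envelope,
* jury ratings drawn around the fitted short-term annoyance curve,
* survey highly-annoyed indicators drawn from the long-term %HA curve,
* a toy receiver grid with a road line source and an overhead flight
  track on 10 m cells.

Every operation is deterministic under its seed; the spectrum
templates themselves are fixed data so downstream numbers are stable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bands import STANDARD_CENTERS, ThirdOctaveSpectrum, energetic_sum
from .constants import LoudnessModelConstants, default_constants
from .loudness import diotic_loudness, diotic_partial_loudness
from .temporal import BinauralAudio
from . import annoyance as _ann

__all__ = [
    "SyntheticScenario",
    "aircraft_spectrum",
    "road_spectrum",
    "flyover_waveform",
    "jury_design",
    "simulate_ratings",
    "simulate_jury",
    "simulate_survey",
    "receiver_grid",
    "AIRCRAFT_LEVELS_DBA",
    "ROAD_LEVELS_DBA",
]

#: Jury/laboratory stimulus level grids, dBA.
AIRCRAFT_LEVELS_DBA = (63.0, 68.0, 73.0, 78.0, 83.0)
ROAD_LEVELS_DBA = (55.0, 60.0, 65.0, 70.0, 75.0)

# Fixed template band shapes (dB relative to the band maximum), one
# value per standard 1/3-octave centre 25 Hz .. 12.5 kHz.  The
# aircraft template tilts toward 1-8 kHz; the road template is
# broadband with most energy between 63 Hz and 1 kHz.
_AIRCRAFT_SHAPE_DB = np.array(
    [-23.0, -20.0, -17.5, -15.5, -14.0, -12.5, -11.0, -9.5, -8.0,
     -7.0, -6.0, -5.0, -4.0, -3.5, -3.0, -3.0, -3.5, -4.0, -2.0,
     -1.0, -0.5, 0.0, 0.0, -0.5, -2.0, -4.0, -7.0, -11.0]
)
_ROAD_SHAPE_DB = np.array(
    [-20.0, -17.0, -14.5, -12.5, -11.0, -9.5, -8.0, -6.5, -5.0,
     -4.0, -3.0, -2.0, -1.0, -0.5, 0.0, 0.0, -0.5, -1.0, -2.0,
     -3.0, -4.0, -5.0, -6.5, -8.0, -10.0, -12.0, -15.0, -18.0]
)


@dataclass(frozen=True)
class SyntheticScenario:
    """The default simulated study conditions."""

    seed: int = 0
    aircraft_levels_dba: tuple = AIRCRAFT_LEVELS_DBA
    road_levels_dba: tuple = ROAD_LEVELS_DBA
    duration_s: float = 20.0
    n_subjects: int = 50
    rating_noise_sd: float = 0.5

    def __post_init__(self):
        if any(not 63.0 <= l <= 83.0 for l in self.aircraft_levels_dba):
            raise ValueError("aircraft levels must lie within 63-83 dBA")
        if any(not 55.0 <= l <= 75.0 for l in self.road_levels_dba):
            raise ValueError("road levels must lie within 55-75 dBA")


def template_spectrum(source: str, level_dba: float) -> ThirdOctaveSpectrum:
    """Template spectrum of a source at any calibrated level.

    Unlike the stimulus-range-checked :func:`aircraft_spectrum` /
    :func:`road_spectrum`, this accepts the low indoor levels that
    exposure mapping produces.
    """
    shapes = {"aircraft": _AIRCRAFT_SHAPE_DB, "road": _ROAD_SHAPE_DB}
    try:
        shape = shapes[source]
    except KeyError:
        raise ValueError(f"unknown source: {source!r}")
    spec = ThirdOctaveSpectrum(np.asarray(STANDARD_CENTERS), shape)
    return spec.calibrate(level_dba)


def aircraft_spectrum(level_dba: float) -> ThirdOctaveSpectrum:
    """Template aircraft flyover spectrum calibrated to ``level_dba``."""
    if not 40.0 <= level_dba <= 100.0:
        raise ValueError("aircraft template level must lie within 40-100 dBA")
    return template_spectrum("aircraft", level_dba)


def road_spectrum(level_dba: float) -> ThirdOctaveSpectrum:
    """Template road-traffic spectrum calibrated to ``level_dba``."""
    if not 40.0 <= level_dba <= 100.0:
        raise ValueError("road template level must lie within 40-100 dBA")
    return template_spectrum("road", level_dba)


def flyover_waveform(
    level_dba: float,
    duration_s: float = 20.0,
    seed: int = 0,
    sample_rate: float = 32000.0,
    interaural_correlation: float = 0.9,
) -> BinauralAudio:
    """Synthetic binaural flyover: shaped noise with a rise-fall envelope.

    The spectrum follows the aircraft template; a raised-cosine
    envelope peaks at mid-file; the two ears carry the same shaped
    noise plus a seeded decorrelated component.  The A-weighted
    equivalent level over the file equals ``level_dba``.
    """
    if duration_s < 5.0:
        raise ValueError("flyover duration must be at least 5 s")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * sample_rate))
    freqs = np.fft.rfftfreq(n, 1.0 / sample_rate)
    centers = np.asarray(STANDARD_CENTERS)
    # amplitude response interpolated from the band template on log-f,
    # rolled off outside the band range
    amp = 10.0 ** (
        np.interp(
            np.log10(np.maximum(freqs, 1.0)),
            np.log10(centers),
            _AIRCRAFT_SHAPE_DB,
            left=-60.0,
            right=-60.0,
        )
        / 20.0
    )
    amp[freqs < 20.0] = 0.0

    def shaped(noise):
        return np.fft.irfft(np.fft.rfft(noise) * amp, n)

    common = rng.standard_normal(n)
    indep = rng.standard_normal(n)
    rho = interaural_correlation
    left = shaped(common)
    right = shaped(rho * common + np.sqrt(1.0 - rho**2) * indep)
    t = np.arange(n) / n
    envelope = 0.5 * (1.0 - np.cos(2.0 * np.pi * t))   # rise-fall, peak mid-file
    audio = BinauralAudio(
        sample_rate, left * envelope, right * envelope, calibration_db=100.0
    )
    return audio.calibrate(level_dba)


# ---------------------------------------------------------------------
# jury simulation
# ---------------------------------------------------------------------

def jury_design(
    aircraft_levels=AIRCRAFT_LEVELS_DBA, road_levels=ROAD_LEVELS_DBA
) -> pd.DataFrame:
    """The 85-condition laboratory design.

    5 aircraft-alone + 5 road-alone + 25 aircraft-with-road (rate the
    aircraft) + 25 road-with-aircraft (rate the road) + 25 combined
    (rate the total).
    """
    rows = []
    for a in aircraft_levels:
        rows.append(("aircraft_alone", "aircraft", a, np.nan))
    for r in road_levels:
        rows.append(("road_alone", "road", np.nan, r))
    for cond, rated in (
        ("aircraft_with_road", "aircraft"),
        ("road_with_aircraft", "road"),
        ("combined", "total"),
    ):
        for a in aircraft_levels:
            for r in road_levels:
                rows.append((cond, rated, a, r))
    return pd.DataFrame(
        rows, columns=["condition", "rated_source", "aircraft_dba", "road_dba"]
    )


def condition_loudness(
    design: pd.DataFrame, constants: LoudnessModelConstants | None = None
) -> np.ndarray:
    """Loudness (sones) of the rated source for every design row.

    Single sources use their unmasked loudness; with-background rows
    use the rated source's partial loudness; combined rows use the
    total loudness of the energetic sum.  Stationary template spectra
    stand in for the recordings.
    """
    c = constants or default_constants()
    out = np.empty(len(design))
    for i, row in enumerate(design.itertuples(index=False)):
        if row.condition == "aircraft_alone":
            out[i] = diotic_loudness(aircraft_spectrum(row.aircraft_dba), c)
        elif row.condition == "road_alone":
            out[i] = diotic_loudness(road_spectrum(row.road_dba), c)
        elif row.condition == "aircraft_with_road":
            out[i] = diotic_partial_loudness(
                aircraft_spectrum(row.aircraft_dba), road_spectrum(row.road_dba), c
            )
        elif row.condition == "road_with_aircraft":
            out[i] = diotic_partial_loudness(
                road_spectrum(row.road_dba), aircraft_spectrum(row.aircraft_dba), c
            )
        elif row.condition == "combined":
            total = energetic_sum(
                aircraft_spectrum(row.aircraft_dba), road_spectrum(row.road_dba)
            )
            out[i] = diotic_loudness(total, c)
        else:
            raise ValueError(f"unknown condition {row.condition!r}")
    return out


def simulate_ratings(
    loudness_sones,
    n_subjects: int = 50,
    noise_sd: float = 0.5,
    rng=None,
) -> np.ndarray:
    """Integer 0-10 ratings for each stimulus loudness.

    Mean rating from the short-term model; per-subject Gaussian noise;
    rounded and clipped to the scale.  Returns an
    ``(n_stimuli, n_subjects)`` integer array.
    """
    if n_subjects < 1:
        raise ValueError("need at least one subject")
    rng = np.random.default_rng(rng)
    mean = _ann.short_term_annoyance(np.asarray(loudness_sones, dtype=float))
    noisy = mean[:, None] + rng.normal(0.0, noise_sd, size=(mean.size, n_subjects))
    return np.clip(np.rint(noisy), 0, 10).astype(int)


def simulate_jury(
    design: pd.DataFrame | None = None,
    n_subjects: int = 50,
    noise_sd: float = 0.5,
    seed: int = 0,
    constants: LoudnessModelConstants | None = None,
) -> pd.DataFrame:
    """Simulated jury experiment: one row per (condition, subject).

    Columns: the design columns plus ``loudness_sone``, ``subject``
    and ``rating``.
    """
    if design is None:
        design = jury_design()
    loud = condition_loudness(design, constants)
    ratings = simulate_ratings(loud, n_subjects, noise_sd, np.random.default_rng(seed))
    frames = []
    for s in range(n_subjects):
        f = design.copy()
        f["loudness_sone"] = loud
        f["subject"] = s
        f["rating"] = ratings[:, s]
        frames.append(f)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------
# survey simulation and toy exposure grid
# ---------------------------------------------------------------------

def simulate_survey(
    grid,
    seed: int = 0,
    constants: LoudnessModelConstants | None = None,
) -> pd.DataFrame:
    """Synthetic resident survey over an exposure grid.

    One record per receiver cell: indoor levels, the loudness triple
    (aircraft partial, road partial, total), a highly-annoyed flag
    drawn Bernoulli from the long-term %HA curve at the total
    loudness, and the exposure group of the combined outdoor level.
    """
    from . import mapping as _mapping

    rng = np.random.default_rng(seed)
    a = np.asarray(grid.aircraft_dba, dtype=float).ravel()
    r = np.asarray(grid.road_dba, dtype=float).ravel()
    records = []
    for i, (la, lr) in enumerate(zip(a, r)):
        loud = _mapping.cell_loudness(la, lr, constants)
        combined = 10.0 * np.log10(10.0 ** (la / 10.0) + 10.0 ** (lr / 10.0))
        p = _ann.long_term_pct_ha(loud.total) / 100.0
        records.append(
            {
                "receiver": i,
                "aircraft_outdoor_dba": la,
                "road_outdoor_dba": lr,
                "aircraft_indoor_dba": _ann.indoor_level(la, "aircraft"),
                "road_indoor_dba": _ann.indoor_level(lr, "road"),
                "aircraft_partial_sone": loud.aircraft_partial,
                "road_partial_sone": loud.road_partial,
                "loudness_sone": loud.total,
                "highly_annoyed": bool(rng.random() < p),
                "group": _mapping.exposure_group(combined),
            }
        )
    return pd.DataFrame(records)


def receiver_grid(
    nx: int = 40,
    ny: int = 40,
    cell_m: float = 10.0,
    road_x_m: float = 100.0,
    road_source_dba: float = 78.0,
    road_decay_db_per_doubling: float = 6.0,
    track_y_m: float = 250.0,
    track_altitude_m: float = 100.0,
    aircraft_source_dba: float = 74.0,
    aircraft_decay_db_per_doubling: float = 10.0,
    reference_m: float = 10.0,
):
    """Toy exposure grid: a road line source plus an overhead flight track.

    Road level decays by a fixed number of dB per doubling of the
    lateral distance to the road axis (flat within ``reference_m``);
    aircraft level decays with the slant distance to the track.  Both
    fields are smooth and bounded; cells are 10 m by default.
    """
    from .mapping import ExposureGrid

    x = (np.arange(nx) + 0.5) * cell_m
    y = (np.arange(ny) + 0.5) * cell_m
    xx, yy = np.meshgrid(x, y)

    d_road = np.maximum(np.abs(xx - road_x_m), reference_m)
    road = road_source_dba - road_decay_db_per_doubling * np.log2(d_road / reference_m)

    slant = np.sqrt((yy - track_y_m) ** 2 + track_altitude_m**2)
    aircraft = aircraft_source_dba - aircraft_decay_db_per_doubling * np.log2(
        slant / track_altitude_m
    )
    return ExposureGrid(
        origin=(0.0, 0.0), cell_m=cell_m, aircraft_dba=aircraft, road_dba=road
    )
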