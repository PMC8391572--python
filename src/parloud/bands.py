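"""Third-octave band spectra, A-weighting and level calibration.

The stationary stimulus description used throughout the package is a
1/3-octave band spectrum: a list of (centre frequency, band level in
dB SPL) pairs on the standard IEC 61260 nominal centre series from
25 Hz to 12.5 kHz.  Levels of ``-inf`` denote silent bands.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: IEC 61260 nominal 1/3-octave centre frequencies, 25 Hz .. 12.5 kHz.
STANDARD_CENTERS: tuple[float, ...] = (
    25.0, 31.5, 40.0, 50.0, 63.0, 80.0, 100.0, 125.0, 160.0, 200.0,
    250.0, 315.0, 400.0, 500.0, 630.0, 800.0, 1000.0, 1250.0, 1600.0,
    2000.0, 2500.0, 3150.0, 4000.0, 5000.0, 6300.0, 8000.0, 10000.0,
    12500.0,
)


def a_weighting_db(freq_hz):
    """IEC 61672 A-weighting in dB at ``freq_hz`` (scalar or array).

    A(1000 Hz) = 0 by construction.
    """
    f = np.asarray(freq_hz, dtype=float)
    f2 = f * f
    num = (12194.0 ** 2) * f2 * f2
    den = (
        (f2 + 20.6 ** 2)
        * np.sqrt((f2 + 107.7 ** 2) * (f2 + 737.9 ** 2))
        * (f2 + 12194.0 ** 2)
    )
    with np.errstate(divide="ignore"):
        a = 20.0 * np.log10(num / den) + 2.000
    return a if a.ndim else float(a)


@dataclass(frozen=True)
class ThirdOctaveSpectrum:
    """Stationary 1/3-octave band spectrum.

    Parameters
    ----------
    centers_hz : array of standard band centre frequencies, strictly
        increasing, each drawn from :data:`STANDARD_CENTERS`.
    levels_db : band levels in dB SPL (``-inf`` allowed for silence).
    """

    centers_hz: np.ndarray
    levels_db: np.ndarray

    def __init__(self, centers_hz, levels_db):
        centers = np.atleast_1d(np.asarray(centers_hz, dtype=float))
        levels = np.atleast_1d(np.asarray(levels_db, dtype=float))
        if centers.size == 0:
            raise ValueError("spectrum must contain at least one band")
        if centers.shape != levels.shape:
            raise ValueError("centers and levels must have equal length")
        if np.any(np.diff(centers) <= 0):
            raise ValueError("band centre frequencies must be strictly increasing")
        standard = np.asarray(STANDARD_CENTERS)
        for c in centers:
            if not np.any(np.isclose(standard, c, rtol=1e-6)):
                raise ValueError(
                    f"non-standard 1/3-octave band centre: {c:g} Hz"
                )
        if np.any(np.isnan(levels)) or np.any(levels == np.inf):
            raise ValueError("band levels must be finite or -inf")
        object.__setattr__(self, "centers_hz", centers)
        object.__setattr__(self, "levels_db", levels)

    def __len__(self) -> int:
        return self.centers_hz.size

    # -- level handling ------------------------------------------------

    def a_weighted_level(self) -> float:
        """A-weighted overall level in dBA (energetic band summation)."""
        w = self.levels_db + a_weighting_db(self.centers_hz)
        finite = w[np.isfinite(w)]
        if finite.size == 0:
            return -np.inf
        return float(10.0 * np.log10(np.sum(10.0 ** (finite / 10.0))))

    def gain(self, gain_db: float) -> "ThirdOctaveSpectrum":
        """Apply a uniform gain in dB, preserving the spectral shape."""
        return ThirdOctaveSpectrum(self.centers_hz, self.levels_db + gain_db)

    def calibrate(self, target_dba: float) -> "ThirdOctaveSpectrum":
        """Uniformly rescale so the A-weighted level equals ``target_dba``.

        Raises ``ValueError`` for silent input (nothing to scale).
        """
        current = self.a_weighted_level()
        if not np.isfinite(current):
            raise ValueError("silent spectrum cannot be calibrated to a level")
        return self.gain(target_dba - current)


def silence(centers_hz=STANDARD_CENTERS) -> ThirdOctaveSpectrum:
    """All-band silence (levels -inf)."""
    centers = np.asarray(centers_hz, dtype=float)
    return ThirdOctaveSpectrum(centers, np.full(centers.size, -np.inf))


def energetic_sum(a: ThirdOctaveSpectrum, b: ThirdOctaveSpectrum) -> ThirdOctaveSpectrum:
    """Incoherent (power) sum of two spectra on the union of their bands."""
    centers = np.union1d(a.centers_hz, b.centers_hz)
    power = np.zeros(centers.size)
    for s in (a, b):
        idx = np.searchsorted(centers, s.centers_hz)
        power[idx] += np.where(
            np.isfinite(s.levels_db), 10.0 ** (s.levels_db / 10.0), 0.0
        )
    with np.errstate(divide="ignore"):
        levels = 10.0 * np.log10(power)
    return ThirdOctaveSpectrum(centers, levels)


def band_edges(center_hz: float) -> tuple[float, float]:
    """Lower and upper band-edge frequencies of a 1/3-octave band."""
    factor = 2.0 ** (1.0 / 6.0)
    return center_hz / factor, center_hz * factor
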