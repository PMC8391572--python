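"""Excitation patterns, (partial) specific loudness, binaural inhibition.

The model family is the ERB-scale loudness model: the stimulus spectrum
is turned into an excitation pattern over auditory channels spaced at
0.25 Cam, the pattern is compressed into specific loudness
``N' = C[(E G + A)^alpha - A^alpha]`` (with a gentler branch below the
threshold excitation), and total loudness is the integral of ``N'``
over the Cam scale.  A target heard against a background gets a
*partial* specific loudness that accounts for masking; the two ears
inhibit each other so that a diotic sound is about 1.5 times as loud
as the same sound in one ear, not twice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bands import ThirdOctaveSpectrum
from .constants import LoudnessModelConstants, default_constants

__all__ = [
    "ExcitationPattern",
    "SpecificLoudnessPattern",
    "excitation_from_components",
    "excitation_from_spectrum",
    "specific_loudness",
    "partial_specific_loudness",
    "integrate_loudness",
    "binaural_inhibition",
    "binaural_loudness",
    "diotic_loudness",
    "diotic_partial_loudness",
    "diotic_tone_loudness",
]


@dataclass(frozen=True)
class ExcitationPattern:
    """Excitation per auditory channel, in linear power units."""

    z: np.ndarray          # channel ERB numbers, Cams (uniformly spaced)
    excitation: np.ndarray
    dz: float

    def __post_init__(self):
        if self.z.shape != self.excitation.shape:
            raise ValueError("channel grid and excitation must align")
        if np.any(self.excitation < 0):
            raise ValueError("excitation must be non-negative")


@dataclass(frozen=True)
class SpecificLoudnessPattern:
    """Specific loudness N' (sones per Cam) per auditory channel."""

    z: np.ndarray
    n_prime: np.ndarray
    dz: float
    role: str = "total"    # total | target_partial | background

    def __post_init__(self):
        if self.z.shape != self.n_prime.shape:
            raise ValueError("channel grid and n_prime must align")

    def __add__(self, other: "SpecificLoudnessPattern") -> "SpecificLoudnessPattern":
        _check_grid(self, other)
        return SpecificLoudnessPattern(self.z, self.n_prime + other.n_prime, self.dz)


def _check_grid(a, b):
    if a.z.shape != b.z.shape or not np.allclose(a.z, b.z) or a.dz != b.dz:
        raise ValueError("patterns are on different channel grids")


# ---------------------------------------------------------------------
# excitation
# ---------------------------------------------------------------------

def excitation_from_components(
    freqs_hz,
    levels_db_spl,
    constants: LoudnessModelConstants | None = None,
    presentation_field: str = "free",
) -> ExcitationPattern:
    """Excitation pattern of a set of sinusoidal components.

    ``levels_db_spl`` may be a 1-D array (one stationary frame) or a
    2-D ``(n_frames, n_components)`` array; the returned excitation is
    then ``(n_frames, n_channels)`` (wrapped patterns are 1-D only, so
    2-D input returns the raw array).  Components at ``-inf`` are
    silent.  Filters are roex with a level-dependent lower slope, so
    the upward spread of excitation grows with component level.
    """
    c = constants or default_constants()
    freqs = np.atleast_1d(np.asarray(freqs_hz, dtype=float))
    levels = np.asarray(levels_db_spl, dtype=float)
    squeeze = levels.ndim == 1
    levels = np.atleast_2d(levels)  # (T, n)
    if levels.shape[1] != freqs.size:
        raise ValueError("levels and component frequencies must align")
    if np.any(levels[np.isfinite(levels)] >= 120.0):
        raise ValueError("component levels must be below 120 dB SPL")

    x = levels + c.transfer_db(freqs, presentation_field)      # effective, (T, n)
    intens = np.where(np.isfinite(x), 10.0 ** (x / 10.0), 0.0)

    # g: deviation of component freq from each channel CF, (n, m)
    g = (freqs[:, None] - c.f_char[None, :]) / c.f_char[None, :]
    lower = g < 0

    # lower slope depends on the component's effective level
    xl = np.where(np.isfinite(x), x, 0.0)                      # (T, n)
    p_l = c.p51[None, None, :] - c.p_level_coeff * (
        c.p51[None, None, :] / c.p51_1k
    ) * (xl[:, :, None] - 51.0)                                # (T, n, m)
    p_l = np.maximum(p_l, c.p_min)
    p = np.where(lower[None, :, :], p_l, c.p51[None, None, :])
    pg = p * np.abs(g)[None, :, :]
    w = (1.0 + pg) * np.exp(-pg)
    e = np.einsum("tn,tnm->tm", intens, w)
    if squeeze:
        return ExcitationPattern(c.z, e[0], c.dz)
    return e


def excitation_from_spectrum(
    spectrum: ThirdOctaveSpectrum,
    presentation_field: str = "free",
    constants: LoudnessModelConstants | None = None,
) -> ExcitationPattern:
    """Excitation pattern of a stationary 1/3-octave spectrum.

    Each band is treated as a single component at its centre frequency.
    """
    return excitation_from_components(
        spectrum.centers_hz, spectrum.levels_db, constants, presentation_field
    )


# ---------------------------------------------------------------------
# specific loudness
# ---------------------------------------------------------------------

def _nprime_unmasked(e, c: LoudnessModelConstants):
    """Specific loudness of an unmasked excitation array (vectorised).

    Above the threshold excitation: ``C[(E G + A)^alpha - A^alpha]``;
    below it the same expression scaled by ``(2E/(E+E_THRQ))^1.5`` so
    loudness falls steeply toward (but only reaches zero at) E = 0.
    """
    e = np.asarray(e, dtype=float)
    core = (e * c.G + c.A) ** c.alpha - c.A ** c.alpha
    with np.errstate(divide="ignore", invalid="ignore"):
        low = np.where(e > 0, (2.0 * e / (e + c.E_THRQ)) ** 1.5, 0.0)
    scale = np.where(e >= c.E_THRQ, 1.0, low)
    return c.C * scale * core


def specific_loudness(
    E: ExcitationPattern, constants: LoudnessModelConstants | None = None
) -> SpecificLoudnessPattern:
    """Unmasked specific loudness of an excitation pattern."""
    c = constants or default_constants()
    if E.z.shape != c.z.shape:
        raise ValueError("excitation pattern grid does not match constants")
    return SpecificLoudnessPattern(E.z, _nprime_unmasked(E.excitation, c), E.dz)


def _nprime_partial(e_sig, e_bg, c: LoudnessModelConstants):
    """Partial specific loudness arrays (target under background)."""
    e_sig = np.asarray(e_sig, dtype=float)
    e_bg = np.asarray(e_bg, dtype=float)
    a_alpha = c.A ** c.alpha
    thrq_term = (c.E_THRQ * c.G + c.A) ** c.alpha

    e_thrn = c.K * e_bg + c.E_THRQ            # masked-threshold excitation

    # target at or above its masked threshold
    masked_bracket = ((e_bg * (1.0 + c.K) + c.E_THRQ) * c.G + c.A) ** c.alpha
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio03 = np.where(
            e_sig > 0, (e_thrn / np.maximum(e_sig, 1e-300)) ** c.partial_exponent, 0.0
        )
    n_above = c.C * (
        ((e_sig + e_bg) * c.G + c.A) ** c.alpha - a_alpha
    ) - c.C * (masked_bracket - thrq_term) * ratio03

    # target below its masked threshold: continuous at E_sig = E_THRN,
    # reduces to the unmasked low-level branch at E_bg = 0
    with np.errstate(divide="ignore", invalid="ignore"):
        lowfac = np.where(
            e_sig > 0, (2.0 * e_sig / (e_sig + e_thrn)) ** 1.5, 0.0
        )
    num = ((e_sig + e_bg) * c.G + c.A) ** c.alpha - (e_bg * c.G + c.A) ** c.alpha
    den = ((e_thrn + e_bg) * c.G + c.A) ** c.alpha - (e_bg * c.G + c.A) ** c.alpha
    n_below = c.C * lowfac * (thrq_term - a_alpha) * num / den

    n = np.where(e_sig >= e_thrn, n_above, n_below)
    # exact no-masker identity, bit for bit
    n = np.where(e_bg == 0.0, _nprime_unmasked(e_sig, c), n)
    # contract: 0 <= partial <= unmasked target loudness
    return np.clip(n, 0.0, _nprime_unmasked(e_sig, c))


def partial_specific_loudness(
    E_target: ExcitationPattern,
    E_background: ExcitationPattern,
    constants: LoudnessModelConstants | None = None,
) -> SpecificLoudnessPattern:
    """Specific loudness of the target heard against the background."""
    c = constants or default_constants()
    _check_grid(E_target, E_background)
    n = _nprime_partial(E_target.excitation, E_background.excitation, c)
    return SpecificLoudnessPattern(E_target.z, n, E_target.dz, role="target_partial")


def integrate_loudness(pattern: SpecificLoudnessPattern) -> float:
    """Integrate loudness density over the Cam scale -> sones."""
    return float(np.sum(pattern.n_prime) * pattern.dz)


# ---------------------------------------------------------------------
# binaural inhibition
# ---------------------------------------------------------------------

def _inhibition_factors(s_ipsi, s_contra, P: float):
    """Effective inhibition factor per channel: 2 / (1 + sech(r))^P.

    ``r`` is the contralateral/ipsilateral ratio of smoothed specific
    loudness.  Where the ipsilateral channel is silent the factor is
    irrelevant (no loudness to inhibit); we return 1 there and the
    caller zeroes the output.
    """
    s_ipsi = np.asarray(s_ipsi, dtype=float)
    s_contra = np.asarray(s_contra, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(s_ipsi > 0, s_contra / np.maximum(s_ipsi, 1e-300), 0.0)
    sech = np.where(r < 700.0, 1.0 / np.cosh(np.minimum(r, 700.0)), 0.0)
    return 2.0 / (1.0 + sech) ** P


def binaural_inhibition(
    S_left: SpecificLoudnessPattern,
    S_right: SpecificLoudnessPattern,
    constants: LoudnessModelConstants | None = None,
    smoothed_left: np.ndarray | None = None,
    smoothed_right: np.ndarray | None = None,
):
    """Apply binaural inhibition to the two ears' specific loudness.

    Each ear's ``N'`` is divided channel-wise by its effective factor
    ``INH = 2 / (1 + sech(S_contra/S_ipsi))^P`` evaluated on smoothed
    patterns (the patterns themselves in stationary use).  Channels
    with zero ipsilateral loudness stay zero.
    """
    c = constants or default_constants()
    _check_grid(S_left, S_right)
    if np.any(S_left.n_prime < 0) or np.any(S_right.n_prime < 0):
        raise ValueError("specific loudness must be non-negative")
    sl = S_left.n_prime if smoothed_left is None else smoothed_left
    sr = S_right.n_prime if smoothed_right is None else smoothed_right
    inh_l = _inhibition_factors(sl, sr, c.P_binaural)
    inh_r = _inhibition_factors(sr, sl, c.P_binaural)
    out_l = np.where(sl > 0, S_left.n_prime / inh_l, 0.0)
    out_r = np.where(sr > 0, S_right.n_prime / inh_r, 0.0)
    return (
        SpecificLoudnessPattern(S_left.z, out_l, S_left.dz, role=S_left.role),
        SpecificLoudnessPattern(S_right.z, out_r, S_right.dz, role=S_right.role),
    )


def binaural_loudness(
    S_left: SpecificLoudnessPattern,
    S_right: SpecificLoudnessPattern,
    constants: LoudnessModelConstants | None = None,
) -> float:
    """Total binaural loudness (sones) with inhibition applied."""
    il, ir = binaural_inhibition(S_left, S_right, constants)
    return integrate_loudness(il) + integrate_loudness(ir)


# ---------------------------------------------------------------------
# stationary conveniences
# ---------------------------------------------------------------------

def diotic_loudness(
    spectrum: ThirdOctaveSpectrum,
    constants: LoudnessModelConstants | None = None,
    presentation_field: str = "free",
) -> float:
    """Binaural loudness of a spectrum presented identically to both ears."""
    c = constants or default_constants()
    e = excitation_from_spectrum(spectrum, presentation_field, c)
    s = specific_loudness(e, c)
    return binaural_loudness(s, s, c)


def diotic_partial_loudness(
    target: ThirdOctaveSpectrum,
    background: ThirdOctaveSpectrum | None,
    constants: LoudnessModelConstants | None = None,
    presentation_field: str = "free",
) -> float:
    """Binaural partial loudness of a diotic target under a diotic background."""
    c = constants or default_constants()
    et = excitation_from_spectrum(target, presentation_field, c)
    if background is None:
        s = specific_loudness(et, c)
        return binaural_loudness(s, s, c)
    eb = excitation_from_spectrum(background, presentation_field, c)
    s = partial_specific_loudness(et, eb, c)
    return binaural_loudness(s, s, c)


def diotic_tone_loudness(
    freq_hz: float,
    level_db_spl: float,
    constants: LoudnessModelConstants | None = None,
) -> float:
    """Binaural loudness of a diotic pure tone (calibration path)."""
    c = constants or default_constants()
    e = excitation_from_components([freq_hz], [level_db_spl], c)
    s = specific_loudness(e, c)
    return binaural_loudness(s, s, c)
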