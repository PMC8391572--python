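"""Equal-loudness level matching and the adaptive up-down procedure.

Given a target sound heard in quiet at a reference level and the same
target heard against a background, the matcher finds the target level
at which the partial loudness under the background equals the loudness
in quiet.  The masked target always needs at least the reference
level, so the matched-minus-reference shift quantifies the masking.
A seeded simulation of the 1-up/1-down staircase with shrinking steps
(5 dB down to 1 dB) reproduces the listening experiment that the
analytic prediction replaces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .bands import ThirdOctaveSpectrum
from .constants import LoudnessModelConstants, default_constants
from . import loudness as _ld
from .loudness import diotic_loudness, diotic_partial_loudness

__all__ = [
    "MatchCondition",
    "StaircaseTrack",
    "predict_equal_level",
    "simulate_staircase",
    "equal_loudness_table",
]


@dataclass(frozen=True)
class MatchCondition:
    """A loudness-match scenario: target in quiet vs target + background."""

    target: ThirdOctaveSpectrum        # shape only; level set per trial
    background: ThirdOctaveSpectrum | None
    reference_dba: float               # target level in quiet
    background_dba: float | None = None

    def __post_init__(self):
        for lv in (self.reference_dba, self.background_dba):
            if lv is not None and not (0.0 <= lv <= 120.0):
                raise ValueError("levels must lie within 0-120 dBA")


@dataclass(frozen=True)
class StaircaseTrack:
    """One simulated adaptive track."""

    levels_dba: np.ndarray             # presented target levels per trial
    responses: tuple                   # 'louder' | 'quieter' | 'same'
    converged_dba: float
    seed: int


def max_long_term_partial_loudness(
    target: ThirdOctaveSpectrum,
    background: ThirdOctaveSpectrum | None,
    constants: LoudnessModelConstants | None = None,
    duration_s: float = 20.0,
    hop_s: float = 0.05,
) -> float:
    """Maximum long-term partial loudness of a flyover-enveloped target.

    The target spectrum is modulated by the raised-cosine flyover
    envelope (normalised so the file's equivalent level equals the
    spectrum's calibrated level, i.e. the peak rides ~4 dB above
    LAeq); the background, if any, is steady.  Per-frame partial
    specific loudness is integrated, inhibition-corrected for diotic
    presentation, and smoothed by the short-/long-term AGC stages; the
    long-term maximum is returned, the representative loudness of a
    time-varying sound.
    """
    from .temporal import _agc

    c = constants or default_constants()
    n = max(int(round(duration_s / hop_s)), 8)
    t = (np.arange(n) + 0.5) / n
    env = 0.5 * (1.0 - np.cos(2.0 * np.pi * t))
    gain = 20.0 * np.log10(np.maximum(env, 1e-4)) - 10.0 * np.log10(
        np.mean(env**2)
    )
    levels = np.minimum(target.levels_db[None, :] + gain[:, None], 119.0)
    et = _ld.excitation_from_components(target.centers_hz, levels, c)
    if background is None:
        npr = _ld._nprime_unmasked(et, c)
    else:
        eb = _ld.excitation_from_spectrum(background, constants=c).excitation
        npr = _ld._nprime_partial(et, np.broadcast_to(eb, et.shape), c)
    inh_diotic = 2.0 / (1.0 + 1.0 / np.cosh(1.0)) ** c.P_binaural
    inst = 2.0 * np.where(npr > 0, npr / inh_diotic, 0.0).sum(axis=1) * c.dz
    steps = max(1, int(round(hop_s * 1000.0 / c.agc["frame_ms"])))
    short = _agc(inst, c.agc["attack_short"], c.agc["release_short"], steps)
    longt = _agc(short, c.agc["attack_long"], c.agc["release_long"], steps)
    return float(np.max(longt))


def _masked_loudness(
    cond: MatchCondition, level_dba: float, c, statistic: str = "max_long_term"
) -> float:
    tgt = cond.target.calibrate(level_dba)
    bg = None
    if cond.background is not None and cond.background_dba is not None:
        bg = cond.background.calibrate(cond.background_dba)
    if statistic == "max_long_term":
        return max_long_term_partial_loudness(tgt, bg, c)
    if statistic == "stationary":
        if bg is None:
            return diotic_loudness(tgt, c)
        return diotic_partial_loudness(tgt, bg, c)
    raise ValueError(f"unknown matching statistic: {statistic!r}")


def reference_loudness(
    cond: MatchCondition, c=None, statistic: str = "max_long_term"
) -> float:
    """Loudness of the target in quiet at the reference level (sones)."""
    c = c or default_constants()
    quiet = MatchCondition(cond.target, None, cond.reference_dba, None)
    return _masked_loudness(quiet, cond.reference_dba, c, statistic)


def predict_equal_level(
    cond: MatchCondition,
    tolerance_db: float = 0.05,
    constants: LoudnessModelConstants | None = None,
    statistic: str = "max_long_term",
) -> float:
    """Target level whose partial loudness equals the quiet reference.

    The matching statistic defaults to the maximum long-term partial
    loudness of the flyover-enveloped target (``"stationary"``
    matches on integrated stationary partial loudness instead).
    Solved by bisection (Brent) on the monotone loudness-vs-level
    objective within [reference - 5, 120] dBA.  Raises ``ValueError``
    when the background is so intense that the target cannot reach the
    reference loudness even at 120 dBA.
    """
    c = constants or default_constants()
    ref = reference_loudness(cond, c, statistic)
    lo, hi = cond.reference_dba - 5.0, 120.0

    def objective(level):
        return _masked_loudness(cond, level, c, statistic) - ref

    f_lo, f_hi = objective(lo), objective(hi)
    if f_lo == 0.0:
        return lo
    if f_hi < 0.0:
        raise ValueError(
            "target stays below the reference loudness up to 120 dBA; "
            "background too intense to match"
        )
    x = brentq(objective, lo, hi, xtol=tolerance_db)
    return float(max(x, cond.reference_dba))


def simulate_staircase(
    cond: MatchCondition,
    subject_noise_sd_db: float = 1.0,
    seed: int = 0,
    constants: LoudnessModelConstants | None = None,
    step_schedule=(5.0, 3.0, 2.0, 1.0),
    same_fraction: float = 0.02,
    max_trials: int = 200,
    statistic: str = "max_long_term",
) -> StaircaseTrack:
    """Simulate a subject running the 1-up/1-down level-match procedure.

    The simulated subject compares the model's partial loudness of the
    presented (noisy) level with the quiet-reference loudness; when the
    subject says the masked sound is louder, the level is reduced on
    the next trial (and vice versa).  Steps shrink from 5 dB to 1 dB at
    each response reversal, and the track ends when the noisy loudness
    difference falls below ``same_fraction`` of the reference loudness.
    """
    if subject_noise_sd_db < 0:
        raise ValueError("subject noise SD must be non-negative")
    c = constants or default_constants()
    rng = np.random.default_rng(seed)
    ref = reference_loudness(cond, c, statistic)
    steps = list(step_schedule)
    if any(b > a for a, b in zip(steps, steps[1:])):
        raise ValueError("step schedule must be non-increasing")

    level = cond.reference_dba + steps[0]   # start with background => louder side
    step_i = 0
    levels, responses = [], []
    prev_dir = 0
    for _ in range(max_trials):
        noisy = _masked_loudness(
            cond, level + rng.normal(0.0, subject_noise_sd_db), c, statistic
        )
        diff = noisy - ref
        levels.append(level)
        if abs(diff) <= same_fraction * ref and step_i == len(steps) - 1:
            responses.append("same")
            break
        if diff > 0:
            responses.append("louder")
            direction = -1
        else:
            responses.append("quieter")
            direction = +1
        if prev_dir != 0 and direction != prev_dir and step_i < len(steps) - 1:
            step_i += 1
        prev_dir = direction
        level = float(np.clip(level + direction * steps[step_i], 0.0, 120.0))
    else:
        responses.append("same")            # forced end of a wandering track
        levels.append(level)
    return StaircaseTrack(
        np.asarray(levels), tuple(responses), float(levels[-1]), seed
    )


def equal_loudness_table(
    target: ThirdOctaveSpectrum,
    background: ThirdOctaveSpectrum,
    reference_levels_dba,
    background_levels_dba,
    tolerance_db: float = 0.05,
    constants: LoudnessModelConstants | None = None,
    statistic: str = "max_long_term",
) -> pd.DataFrame:
    """Predicted matched level for every (reference, background) pair.

    Returns a table with columns ``target_db, background_db,
    predicted_db, shift_db`` (shift = predicted - reference, >= 0).
    An empty background list yields identity matches.
    """
    if len(list(reference_levels_dba)) == 0:
        raise ValueError("reference level list must be non-empty")
    c = constants or default_constants()
    rows = []
    bg_levels = list(background_levels_dba) or [None]
    for ref in reference_levels_dba:
        for bg in bg_levels:
            cond = MatchCondition(
                target, background if bg is not None else None, float(ref), bg
            )
            pred = predict_equal_level(cond, tolerance_db, c, statistic)
            rows.append(
                {
                    "target_db": float(ref),
                    "background_db": float(bg) if bg is not None else np.nan,
                    "predicted_db": pred,
                    "shift_db": max(pred - float(ref), 0.0),
                }
            )
    return pd.DataFrame(rows)
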