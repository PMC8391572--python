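"""Loudness-model constants: channel grid, gains, thresholds, filters.

The bundle is loaded from a YAML data file (packaged default under
``parloud/data/loudness_constants.yaml``) and turned into per-channel
arrays on the ERB-number (Cam) grid.  The scaling constant ``C`` is
computed once per bundle from the calibration convention that a 1 kHz
pure tone at 40 dB SPL heard diotically is 1 sone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml


def cam_from_hz(f):
    """ERB-number (Cam) of frequency ``f`` in Hz."""
    return 21.366 * np.log10(0.004368 * np.asarray(f, dtype=float) + 1.0)


def hz_from_cam(z):
    """Frequency in Hz at ERB-number ``z`` Cams."""
    return (10.0 ** (np.asarray(z, dtype=float) / 21.366) - 1.0) / 0.004368


def erb_hz(f):
    """Equivalent rectangular bandwidth in Hz at frequency ``f``."""
    return 24.673 * (0.004368 * np.asarray(f, dtype=float) + 1.0)


def _interp_logf(f, table_f, table_v):
    """Linear interpolation on a log-frequency axis, clamped at the ends."""
    return np.interp(np.log10(np.asarray(f, dtype=float)), np.log10(table_f), table_v)


@dataclass
class LoudnessModelConstants:
    """Per-channel constant tables for the loudness model.

    Attributes are arrays over the channel grid unless noted.
    ``C`` is the overall sone scaling; ``A`` and ``alpha`` the
    additive constant and compressive exponent of the specific-loudness
    transform; ``G`` the linear cochlear gain; ``E_THRQ`` the linear
    peak excitation at absolute threshold; ``K`` the linear
    signal-to-noise ratio at masked threshold.
    """

    z: np.ndarray              # channel ERB numbers, Cams
    f_char: np.ndarray         # channel characteristic frequencies, Hz
    dz: float                  # channel spacing, Cams
    G: np.ndarray              # linear cochlear gain per channel
    G_db: np.ndarray
    E_THRQ: np.ndarray         # linear excitation at absolute threshold
    A: np.ndarray
    alpha: np.ndarray
    K: np.ndarray              # linear SNR at masked threshold
    p51: np.ndarray            # roex slope at 51 dB per channel
    p51_1k: float
    p_level_coeff: float
    p_min: float
    C: float
    E0_db: float
    partial_exponent: float
    P_binaural: float
    maf_freq: np.ndarray
    maf_db: np.ndarray
    diffuse_freq: np.ndarray
    diffuse_db: np.ndarray
    agc: dict
    binaural_smooth_tau_ms: float
    raw: dict = field(repr=False, default_factory=dict)

    # -- construction --------------------------------------------------

    @classmethod
    def from_dict(cls, cfg: dict) -> "LoudnessModelConstants":
        grid = cfg["channel_grid"]
        dz = float(grid["dz_cam"])
        z = np.arange(grid["z_min_cam"], grid["z_max_cam"] + dz / 2, dz)
        f_char = hz_from_cam(z)

        z500 = cam_from_hz(500.0)
        g_db = np.where(
            f_char >= 500.0,
            0.0,
            -float(cfg["g_slope_db_per_cam"]) * (z500 - z),
        )
        g_db = np.maximum(g_db, float(cfg["g_floor_db"]))
        alpha = float(cfg["alpha_mid"]) + float(cfg["alpha_per_db_gain"]) * g_db
        A = float(cfg["A_mid"]) + float(cfg["A_per_db_gain"]) * g_db
        e0_db = float(cfg["E0_db"])
        e_thrq = 10.0 ** ((e0_db - g_db) / 10.0)
        k_db = _interp_logf(
            f_char, cfg["K_table"]["freq_hz"], cfg["K_table"]["K_db"]
        )
        p51 = 4.0 * f_char / erb_hz(f_char)
        p51_1k = float(4.0 * 1000.0 / erb_hz(1000.0))

        obj = cls(
            z=z,
            f_char=f_char,
            dz=dz,
            G=10.0 ** (g_db / 10.0),
            G_db=g_db,
            E_THRQ=e_thrq,
            A=A,
            alpha=alpha,
            K=10.0 ** (k_db / 10.0),
            p51=p51,
            p51_1k=p51_1k,
            p_level_coeff=float(cfg["p_level_coeff"]),
            p_min=float(cfg["p_min"]),
            C=1.0,
            E0_db=e0_db,
            partial_exponent=float(cfg["partial_exponent"]),
            P_binaural=float(cfg["P_binaural"]),
            maf_freq=np.asarray(cfg["maf_table"]["freq_hz"], dtype=float),
            maf_db=np.asarray(cfg["maf_table"]["threshold_db"], dtype=float),
            diffuse_freq=np.asarray(cfg["diffuse_correction"]["freq_hz"], dtype=float),
            diffuse_db=np.asarray(cfg["diffuse_correction"]["delta_db"], dtype=float),
            agc=dict(cfg["agc"]),
            binaural_smooth_tau_ms=float(cfg["binaural_smooth_tau_ms"]),
            raw=cfg,
        )
        obj.C = cfg.get("C") or obj._calibrate_C()
        return obj

    @classmethod
    def from_yaml(cls, path) -> "LoudnessModelConstants":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def default(cls) -> "LoudnessModelConstants":
        ref = resources.files("parloud.data") / "loudness_constants.yaml"
        return cls.from_dict(yaml.safe_load(ref.read_text()))

    # -- derived helpers ----------------------------------------------

    def threshold_db(self, f) -> np.ndarray:
        """Free-field hearing threshold (MAF) in dB SPL at ``f``."""
        return _interp_logf(f, self.maf_freq, self.maf_db)

    def transfer_db(self, f, presentation_field: str = "free") -> np.ndarray:
        """Outer/middle-ear + gain-referenced transfer in dB.

        Defined so that a tone at the hearing threshold produces peak
        excitation ``E_THRQ`` at its own characteristic frequency.
        """
        f = np.asarray(f, dtype=float)
        z500 = cam_from_hz(500.0)
        g_db = np.where(
            f >= 500.0,
            0.0,
            -float(self.raw["g_slope_db_per_cam"]) * (z500 - cam_from_hz(f)),
        )
        g_db = np.maximum(g_db, float(self.raw["g_floor_db"]))
        t = self.E0_db - g_db - self.threshold_db(f)
        if presentation_field == "diffuse":
            t = t - _interp_logf(f, self.diffuse_freq, self.diffuse_db)
        elif presentation_field != "free":
            raise ValueError(f"unknown presentation field: {presentation_field!r}")
        return t

    def _calibrate_C(self) -> float:
        # local import to avoid a cycle at module import time
        from . import loudness

        self.C = 1.0
        ref = loudness.diotic_tone_loudness(1000.0, 40.0, self)
        if not ref > 0:
            raise RuntimeError("calibration tone produced zero loudness")
        return 1.0 / ref


_DEFAULT: LoudnessModelConstants | None = None


def default_constants() -> LoudnessModelConstants:
    """Shared default constants bundle (lazily built and cached)."""
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = LoudnessModelConstants.default()
    return _DEFAULT
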