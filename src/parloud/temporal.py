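"""Time-varying loudness: framed spectra, AGC smoothing, loudness traces.

A calibrated binaural waveform is analysed frame by frame: each
frame's spectrum is reduced to 1/3-octave band levels, run through the
excitation/specific-loudness chain, and binaural inhibition is applied
using a smoothed short-term specific-loudness estimate.  The
instantaneous loudness series is then smoothed twice by asymmetric
(attack faster than release) automatic-gain-control stages to give
short-term and long-term loudness; the maximum of the long-term series
is the representative single number for a time-varying sound.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.io import wavfile
from scipy.signal import stft

from .bands import STANDARD_CENTERS, a_weighting_db, band_edges
from .constants import LoudnessModelConstants, default_constants
from . import loudness as _ld

__all__ = [
    "BinauralAudio",
    "LoudnessTrace",
    "time_varying_loudness",
    "a_weighted_level",
    "read_wav",
    "write_wav",
]


@dataclass(frozen=True)
class BinauralAudio:
    """Two-channel PCM audio with an absolute level calibration.

    ``calibration_db`` is the dB SPL of a full-scale (peak amplitude
    1.0) sine wave; it ties the dimensionless samples to sound
    pressure.  ``None`` marks uncalibrated audio, which the loudness
    path rejects.
    """

    sample_rate: float
    left: np.ndarray
    right: np.ndarray
    calibration_db: float | None = 100.0

    def __post_init__(self):
        if self.left.shape != self.right.shape:
            raise ValueError("left and right channels must have equal length")
        if not self.sample_rate > 8000.0:
            raise ValueError("sample rate must exceed 8 kHz")

    @property
    def duration(self) -> float:
        return self.left.size / self.sample_rate

    def gain(self, gain_db: float) -> "BinauralAudio":
        g = 10.0 ** (gain_db / 20.0)
        return BinauralAudio(
            self.sample_rate, self.left * g, self.right * g, self.calibration_db
        )

    def calibrate(self, target_dba: float) -> "BinauralAudio":
        """Uniform gain so the A-weighted equivalent level equals target."""
        current = a_weighted_level(self)
        if not np.isfinite(current):
            raise ValueError("silent audio cannot be calibrated to a level")
        return self.gain(target_dba - current)


@dataclass(frozen=True)
class LoudnessTrace:
    """Instantaneous / short-term / long-term loudness time series."""

    dt: float                  # seconds per frame
    instantaneous: np.ndarray  # sones
    short_term: np.ndarray
    long_term: np.ndarray

    def __post_init__(self):
        n = self.instantaneous.size
        if self.short_term.size != n or self.long_term.size != n:
            raise ValueError("all loudness series must have equal length")

    @property
    def max_long_term(self) -> float:
        return float(np.max(self.long_term)) if self.long_term.size else 0.0

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.instantaneous.size) * self.dt


# ---------------------------------------------------------------------
# framed band levels
# ---------------------------------------------------------------------

def _frame_band_levels(
    x: np.ndarray,
    fs: float,
    calibration_db: float,
    hop_s: float,
    window_s: float = 0.064,
):
    """Per-frame 1/3-octave band levels (dB SPL) of one channel.

    Hann STFT; FFT-bin powers are pooled into the standard bands.  A
    full-scale sine maps to ``calibration_db`` dB SPL.
    """
    nper = int(round(window_s * fs))
    hop = max(1, int(round(hop_s * fs)))
    f, t, Z = stft(
        x, fs=fs, window="hann", nperseg=nper, noverlap=nper - hop,
        boundary="zeros", padded=True,
    )
    # scipy's stft normalises so a unit-amplitude sine gives |Z| = 0.5
    # at its bin; power per bin (mean-square contribution) = 2|Z|^2.
    power = 2.0 * np.abs(Z) ** 2                       # (F, T)
    enbw = 1.5                                         # Hann noise bandwidth, bins
    centers = np.asarray(STANDARD_CENTERS)
    bands = np.zeros((t.size, centers.size))
    for i, c in enumerate(centers):
        lo, hi = band_edges(c)
        sel = (f >= lo) & (f < hi)
        if not np.any(sel):            # band narrower than one FFT bin
            sel = np.argmin(np.abs(f - c))
            bands[:, i] = power[sel, :]
        else:
            bands[:, i] = power[sel, :].sum(axis=0) / enbw
    with np.errstate(divide="ignore"):
        # mean-square ms of a sine of amplitude a is a^2/2 -> SPL =
        # cal + 10 log10(2 ms)
        levels = calibration_db + 10.0 * np.log10(2.0 * bands)
    return centers, levels, hop / fs


def _agc(x: np.ndarray, attack: float, release: float, steps: int = 1):
    """Asymmetric one-pole smoother (attack when rising, release when
    falling), applied ``steps`` sub-steps per frame so coefficients
    defined per 1 ms remain valid at coarser hops."""
    y = np.empty_like(x)
    prev = 0.0
    for i, v in enumerate(x):
        for _ in range(steps):
            coeff = attack if v > prev else release
            prev = coeff * v + (1.0 - coeff) * prev
        y[i] = prev
    return y


def _two_sided_exp_smooth(x: np.ndarray, tau_frames: float):
    """Two-sided exponential smoothing along axis 0 (frames)."""
    if tau_frames <= 0:
        return x
    a = 1.0 - np.exp(-1.0 / tau_frames)
    fwd = np.empty_like(x)
    acc = np.zeros(x.shape[1:])
    for i in range(x.shape[0]):
        acc = a * x[i] + (1 - a) * acc
        fwd[i] = acc
    bwd = np.empty_like(x)
    acc = np.zeros(x.shape[1:])
    for i in range(x.shape[0] - 1, -1, -1):
        acc = a * x[i] + (1 - a) * acc
        bwd[i] = acc
    return 0.5 * (fwd + bwd)


def time_varying_loudness(
    audio: BinauralAudio,
    constants: LoudnessModelConstants | None = None,
    hop_s: float | None = None,
    presentation_field: str = "free",
) -> LoudnessTrace:
    """Loudness trace of calibrated binaural audio.

    The default hop is the constants bundle's AGC frame (1 ms);
    coarser hops rescale the AGC update accordingly.
    """
    c = constants or default_constants()
    if audio.calibration_db is None:
        raise ValueError("audio has no dB SPL calibration; cannot compute loudness")
    if hop_s is None:
        hop_s = c.agc["frame_ms"] / 1000.0
    if audio.duration < 0.064:
        raise ValueError("audio shorter than one analysis frame")

    inh_patterns = []
    smoothed = []
    for x in (audio.left, audio.right):
        centers, levels, dt = _frame_band_levels(
            np.asarray(x, dtype=float), audio.sample_rate, audio.calibration_db, hop_s
        )
        levels = np.minimum(levels, 119.9)     # guard the excitation precondition
        e = _ld.excitation_from_components(centers, levels, c, presentation_field)
        inh_patterns.append(_ld._nprime_unmasked(e, c))
    tau_frames = c.binaural_smooth_tau_ms / 1000.0 / dt
    smoothed = [_two_sided_exp_smooth(p, tau_frames) for p in inh_patterns]

    inst = np.zeros(inh_patterns[0].shape[0])
    for ipsi, (n, s) in enumerate(zip(inh_patterns, smoothed)):
        s_contra = smoothed[1 - ipsi]
        inh = _ld._inhibition_factors(s, s_contra, c.P_binaural)
        inhibited = np.where(s > 0, n / inh, 0.0)
        inst += inhibited.sum(axis=1) * c.dz

    steps = max(1, int(round(dt * 1000.0 / c.agc["frame_ms"])))
    short = _agc(inst, c.agc["attack_short"], c.agc["release_short"], steps)
    longt = _agc(short, c.agc["attack_long"], c.agc["release_long"], steps)
    return LoudnessTrace(dt, inst, short, longt)


# ---------------------------------------------------------------------
# levels and WAV I/O
# ---------------------------------------------------------------------

def a_weighted_level(audio: BinauralAudio) -> float:
    """A-weighted equivalent level (LAeq, dBA) over the whole file,
    energetically averaged across the two ears."""
    if audio.calibration_db is None:
        raise ValueError("audio has no dB SPL calibration")
    total = 0.0
    for x in (audio.left, audio.right):
        x = np.asarray(x, dtype=float)
        spec = np.fft.rfft(x)
        freqs = np.fft.rfftfreq(x.size, 1.0 / audio.sample_rate)
        # mean-square per bin; one-sided spectrum
        power = (np.abs(spec) ** 2) / x.size**2
        power[1:] *= 2.0
        w = 10.0 ** (a_weighting_db(np.maximum(freqs, 1e-6)) / 10.0)
        ms = float(np.sum(power * w))
        total += ms
    ms = total / 2.0
    if ms <= 0:
        return -np.inf
    return audio.calibration_db + 10.0 * np.log10(2.0 * ms)


def read_wav(path, calibration_db: float | None) -> BinauralAudio:
    """Read a 2-channel WAV (PCM 16/24/32-bit or float) as BinauralAudio."""
    fs, data = wavfile.read(path)
    if data.ndim == 1:
        data = np.stack([data, data], axis=1)
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(float) / float(np.iinfo(data.dtype).max)
    else:
        data = data.astype(float)
    return BinauralAudio(float(fs), data[:, 0], data[:, 1], calibration_db)


def write_wav(path, audio: BinauralAudio) -> None:
    """Write BinauralAudio as a float32 WAV."""
    data = np.stack([audio.left, audio.right], axis=1).astype(np.float32)
    wavfile.write(path, int(audio.sample_rate), data)
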