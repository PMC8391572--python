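# Loudness-model constants bundle (Moore-Glasberg lineage reconstruction).
#
# The excitation/specific-loudness machinery follows the ERB-scale
# partial-loudness model family: roex excitation patterns with a
# level-dependent lower slope, a compressive specific-loudness
# transform N' = C[(E G + A)^alpha - A^alpha] with a low-level branch,
# four-case partial loudness, and binaural inhibition.  The scaling
# constant C is not stored: it is computed at load time from the
# model's own calibration convention (a 1 kHz pure tone at 40 dB SPL,
# presented diotically, has a loudness of exactly 1 sone).
#
# All tables are overridable; frequencies in Hz, levels in dB.

channel_grid:
  z_min_cam: 1.75     # ~50 Hz
  z_max_cam: 39.0     # ~15 kHz
  dz_cam: 0.25

# Compressive exponent and additive constant at mid/high frequencies
# (cochlear gain G = 0 dB); both grow as the gain falls off at low
# frequencies (linear interpolation in G).
alpha_mid: 0.2
alpha_per_db_gain: -0.00268      # alpha = alpha_mid + coeff * G_db
A_mid: 4.72
A_per_db_gain: -0.36             # A = A_mid + coeff * G_db

# Peak excitation at the absolute threshold, dB, for f >= 500 Hz;
# below 500 Hz the threshold excitation rises as the gain falls.
E0_db: 3.63

# Cochlear gain: 0 dB at and above 500 Hz, falling linearly on the
# Cam scale below, floored.
g_slope_db_per_cam: 2.8
g_floor_db: -25.0

# roex filter shapes: p51 = 4 f / ERB(f); the lower slope shallows
# with component level X as p_l = p51 - p_level_coeff*(p51/p51_1k)*(X-51).
p_level_coeff: 0.35
p_min: 1.0

# Partial-loudness fixed exponent and binaural-inhibition exponent.
partial_exponent: 0.3
P_binaural: 1.598

# Signal-to-noise ratio at masked threshold, dB, vs frequency
# (high at low frequencies, small negative asymptote).
K_table:
  freq_hz:  [50,   100,  200,  400,  800,  1600, 3200, 6400, 16000]
  K_db:     [13.0, 9.0,  5.5,  2.5,  0.0, -1.5, -2.5, -3.0, -3.0]

# Free-field minimum audible field (hearing threshold), dB SPL.
maf_table:
  freq_hz: [20, 25, 31.5, 40, 50, 63, 80, 100, 125, 160, 200, 250,
            315, 400, 500, 630, 800, 1000, 1250, 1600, 2000, 2500,
            3150, 4000, 5000, 6300, 8000, 10000, 12500, 15000, 18000]
  threshold_db: [78.5, 68.7, 59.5, 51.1, 44.0, 37.5, 31.5, 26.5,
                 22.1, 17.9, 14.4, 11.4, 8.6, 6.2, 4.4, 3.0, 2.2,
                 2.4, 3.5, 1.7, -1.3, -4.2, -6.0, -5.4, -1.5, 4.3,
                 12.6, 13.9, 12.3, 25.0, 55.0]

# Diffuse-field minus free-field threshold difference (applied when
# the presentation field is "diffuse"); zero elsewhere.
diffuse_correction:
  freq_hz: [500, 1000, 2000, 3150, 4000, 5000, 6300, 8000, 12500]
  delta_db: [0.0, 0.3, 1.5, 2.5, 2.5, 2.0, 1.0, -1.5, -2.0]

# Automatic-gain-control time constants for the time-varying path,
# expressed as per-1-ms smoothing coefficients (attack < release in
# time-constant terms, i.e. attack coefficient is the larger).
agc:
  frame_ms: 1.0
  attack_short: 0.045
  release_short: 0.02
  attack_long: 0.01
  release_long: 0.0005

# Two-sided exponential smoother width for the binaural-inhibition
# "smoothed short-term specific loudness", in ms.
binaural_smooth_tau_ms: 50.0
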