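# Methods

## Loudness model

The acoustic core is a loudness model in the Moore–Glasberg (ERB-scale)
lineage, reconstructed and calibrated rather than copied from a
published constants table.

**Channel grid.** 150 auditory channels at 0.25-Cam spacing from 1.75
to 39 Cams (≈48 Hz–15 kHz), with `z(f) = 21.366·log₁₀(0.004368 f + 1)`
and `ERB(f) = 24.673(0.004368 f + 1)` Hz.

**Excitation patterns.** Each 1/3-octave band of a stationary spectrum
is treated as one sinusoidal component at its centre frequency
(standard practice for band-spectrum input).  Components pass through
a transfer function defined so that a tone at the free-field hearing
threshold produces the threshold excitation at its own characteristic
frequency; the threshold curve is the standard minimum-audible-field
table, linearly interpolated on log-frequency (a diffuse-field
correction table is applied when requested).  Excitation at each
channel is the sum of component intensities weighted by roex filters
`W(g) = (1 + p|g|)e^(−p|g|)`.  The upper slope is fixed at
`p51 = 4f/ERB(f)`; the lower slope shallows with component level as
`p_l = p51 − 0.35(p51/p51,1k)(X − 51)` (floored at 1), which produces
the upward spread of masking and, with the compressive transform
below, the classic loudness growth rate.

**Specific loudness.** For excitation at or above the channel's
threshold excitation, `N′ = C[(E·G + A)^α − A^α]`; below it the same
expression is scaled by `(2E/(E + E_THRQ))^1.5` so loudness falls
steeply toward zero at silence.  Cochlear gain `G` is 0 dB at and
above 500 Hz and falls at 2.8 dB/Cam below (floored at −25 dB);
`α = 0.2` and `A = 4.72` at mid frequencies, both increasing as the
gain falls.  The threshold excitation is 3.63 dB (in gain-referenced
units) at and above 500 Hz, rising below in step with the gain loss.
The scale constant `C` is not a stored number: it is computed at
load time from the model's own calibration convention — a 1 kHz
diotic tone at 40 dB SPL is exactly 1 sone.  With these choices the
model also reproduces loudness doubling per 10 dB (measured ratios
2.08 and 1.98 between 40–60 dB SPL), which was *not* imposed.

**Partial loudness.** A target against a background is evaluated per
channel against the masked-threshold excitation
`E_THRN = K·E_BG + E_THRQ`, where `K` is the signal-to-noise ratio at
masked threshold (13 dB at 50 Hz falling to −3 dB above ~6 kHz,
log-frequency interpolated).  Above the masked threshold:

    N′ = C[((E_SIG+E_BG)G + A)^α − A^α]
       − C[((E_BG(1+K)+E_THRQ)G + A)^α − ((E_THRQ)G + A)^α]·(E_THRN/E_SIG)^0.3

Below it, a form chosen to be continuous at `E_SIG = E_THRN` and to
reduce bit-exactly to the unmasked low-level branch at `E_BG = 0`:

    N′ = C·(2E_SIG/(E_SIG+E_THRN))^1.5
       · [(E_THRQ·G + A)^α − A^α]
       · [((E_SIG+E_BG)G + A)^α − (E_BG·G + A)^α]
       / [((E_THRN+E_BG)G + A)^α − (E_BG·G + A)^α]

The result is clipped into `[0, unmasked N′]`; near the masked
threshold the reconstruction can stray a hair outside the contract
envelope.  The >120 dB SPL very-high-level branch is not implemented;
inputs are rejected above that (outside the domain of every use here).

**Binaural inhibition.** Each ear's specific loudness is divided by
`INH = 2/(1 + sech(S_contra/S_ipsi))^P` with `P = 1.598`, evaluated on
smoothed short-term patterns (the patterns themselves in stationary
use; a two-sided 50 ms exponential smoother across frames in
time-varying use).  Channels with zero ipsilateral loudness output
zero.  Consequences: monaural loudness is boosted by `2^(P−1)`;
diotic presentation gets the factor 0.900 per ear; the
diotic/monaural ratio is 1.47.

**Time-varying loudness.** Frame spectra come from a 64 ms Hann STFT
(noise-bandwidth corrected) pooled into 1/3-octave bands, with a
configurable hop (default 1 ms, the AGC's native step; analyses use
2–50 ms hops where the signals are slowly modulated).  Instantaneous
loudness per frame feeds two asymmetric one-pole AGC stages —
short-term (attack 0.045, release 0.02 per ms) then long-term (0.01,
0.0005) — and the maximum of the long-term series is the
representative loudness of an event.  A steady tone's long-term
maximum agrees with its stationary loudness within 3 %.

## Equal-loudness matching

The matcher finds, by Brent bisection over [reference − 5, 120] dBA
(tolerance 0.05 dB), the target level whose loudness under the
background equals the target's loudness in quiet at the reference
level.  The default matching statistic is the **maximum long-term
partial loudness** of the flyover-enveloped target over the steady
background (the quiet reference uses the same statistic): an event
statistic, because the listening situation compares a 20 s flyover
with steady traffic, and at the flyover peak the target rides ≈4 dB
above its own LAeq, which is precisely why a background 20+ dB below
the target barely moves the match.  A `stationary` statistic
(integrated stationary partial loudness) is available and is used in
tight simulation loops.  The staircase simulation mirrors the
adaptive procedure: 1-up/1-down on the model loudness perturbed by
Gaussian level noise, steps shrinking 5→3→2→1 dB at response
reversals, "same" declared when the loudness difference falls below
2 % of the reference (the equal-judgement criterion is a package
choice; nothing in the procedure's description fixes it).

## Annoyance models

Both fitted curves are the generalised logistic
`f(x) = L/(1 + e^{−k(x−x₀)})`, carried in the algebraically identical
reciprocal form `1/(1/L + a·bˣ)` (`a = e^{kx₀}/L`, `b = e^{−k}`):
short-term rating `1/(0.1 + 0.463·0.936^N)` (maximum 10) and
long-term `%HA = 1/(0.01 + 0.043·0.97^N)` (maximum 100, floor 18.9 %
at zero loudness — some residents are highly annoyed regardless).
The reciprocal reading of the printed coefficient sets is a
reconstruction (the source typography collapses the fraction bars);
it is the unique reading consistent with the logistic family, the
scale maxima, and the nonzero %HA at zero loudness.

"Highly annoyed" is a rating of **8 or more** on the 0–10 scale (the
conventional top-27 % cutoff; "more than eight" is ambiguous and the
cutoff is configurable).  Refitting uses Levenberg–Marquardt on
(L, a, b) with bounds `b ∈ (0,1)`, `a > 0` and `L` bounded by the
response-scale maximum (10 or 100) — the scale bound is part of the
model definition and is what keeps `L` identified when the data never
approach the ceiling.  Initialisation: `L` at the scale maximum, (a, b)
from a log-linear regression of `log(1/y − 1/L)`.  R² is
`1 − SS_res/SS_tot` on the fitted response scale.  Loudness binning is
anchored at 0 with half-open 5-sone intervals.

## RLS-90 road emission

Implemented exactly as printed: `Lm,E = 37.3 + 10log₁₀[Q(1+0.082P)]`,
speed correction via `L_car = 27.7 + 10log₁₀[1+(0.02v)³]`,
`L_truck = 23.1 + 12.5log₁₀(v)` (null at the 100/80 km/h reference
speeds for every truck share), gradient correction `0.6g − 3` above
5 %, and `Lr = Lm + K`.  All logs are base-10.  The surface, building,
distance, ground and topography corrections are named but not defined
in the source material; they are accepted as per-segment inputs
defaulting to zero, with a documented free-field line-source helper
for toy grids that is explicitly beyond the guideline text.
Multi-lane combination is energetic.  Day/night traffic-count
weighting is a data-collection step and is not implemented.

## Synthetic study conditions

The generator reproduces the study's *conditions*, not its recordings:

- **Templates** are fixed band-shape arrays (never random).  Both
  sources share a broadband base peaking near 630–800 Hz in SPL
  terms; the aircraft adds a high-frequency plateau at 2–5 kHz (its
  4 kHz band is ~9 dB above its 125 Hz band), the road rolls off
  above 1 kHz.  This near-parallel low-mid structure, typical of
  A-weighted transportation spectra, is what makes a 23 dB level gap
  translate into ≥20 dB of per-channel signal-to-noise everywhere the
  target carries loudness.  Stimulus levels follow the laboratory
  grids: aircraft 63–83 dBA, road 55–75 dBA in 5 dB steps.
- **Flyovers** are spectrum-shaped noise under a raised-cosine
  envelope peaking mid-file (default 20 s, the recording length),
  ears decorrelated to 0.9, LAeq calibrated to the nominal level.
- **Jury**: the 85-condition design (5 aircraft-alone, 5 road-alone,
  25 rate-aircraft-with-road, 25 rate-road-with-aircraft, 25
  combined), 50 subjects, mean ratings from the short-term curve plus
  Gaussian noise of SD 0.5 scale points (the source reports no
  inter-subject variance; 0.5 points is a typical rating-scale
  repeatability), rounded and clipped to 0–10.  Condition loudness is
  computed in stationary mode from the templates.
- **Survey**: per receiver, indoor levels, the partial-loudness
  triple, and a highly-annoyed flag drawn Bernoulli from the
  long-term curve at the total loudness; exposure groups are
  <50 / 50–60 / 60–70 / ≥70 dBA with ties assigned upward.
- **Toy grid**: 10 m cells, a road line source losing a fixed number
  of dB per doubling of lateral distance and a flight track losing
  per doubling of slant distance — smooth, bounded stand-ins for the
  propagation models that produced the real maps.

What the synthetic conditions do *not* emulate: real source spectra
(the recorded bands are unpublished), propagation geometry, barriers
and reflections, non-acoustic moderators of annoyance, and
inter-subject rating structure beyond i.i.d. Gaussian noise.  Passing
tests therefore demonstrate the *self-consistency and contracts* of
the chain (masking monotonicity and asymmetry, calibration anchors,
coefficient recovery), not field validity.

## Mapping

Per cell: indoor corrections first (−15 dBA aircraft, −15.8 dBA road;
indoor levels ≤0 dBA contribute no excitation), template spectra at
the indoor levels, stationary partial loudness of each source with
the other as masker, total loudness of the energetic sum, then the
long-term curve on each loudness layer.  Stationary treatment is the
package's choice for annual-average LAeq inputs.  Cell results are
cached on levels quantised to 0.01 dB so large rasters stay cheap.

## Numerical choices and problem sizes

- Bisection tolerance 0.05 dB; matcher event statistic at 50 ms hops
  over a 20 s envelope.
- The `sech` argument is cut off at 700 (beyond double-precision
  underflow); where ipsilateral loudness is zero the inhibited output
  is defined as zero.
- Fit initialisation clips `1/y − 1/L` at 1e−9 before the log-linear
  regression; non-convergence raises, never silently returns.
- Coefficient-recovery runs use 20 replicates and the sample sizes of
  the study design (50 subjects/stimulus; 2000 draws/bin, the survey's
  order of magnitude); the toy-map analyses use 40×40–60×60 grids.
  These sizes keep every analysis desk-scale while leaving the
  Monte-Carlo error well inside the reported tolerances.

## Known limitations

- The loudness constants are a calibrated reconstruction of the
  referenced model family, not a certified implementation of any
  standard; absolute sone values for broadband sounds may differ from
  standard implementations by more than the anchored tone cases.
- Eq.-level fidelity of the partial-loudness casework below masked
  threshold is a reconstruction constrained by continuity and limits
  rather than a printed formula.
- Binaural inhibition is applied to whichever specific-loudness
  patterns the caller designates as "smoothed"; in stationary use the
  unsmoothed patterns stand in.
- The matcher's event statistic assumes the synthetic raised-cosine
  envelope; real flyovers have flatter, noisier envelopes.
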