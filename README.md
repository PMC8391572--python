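# parloud — partial-loudness annoyance modelling for combined noise

People living near airports are rarely exposed to aircraft noise
alone: road traffic runs underneath the flight paths, and each source
partially **masks** the other.  Energy-based indicators (LAeq,
day-night levels) cannot express this — two exposures with identical
levels can be heard, and resented, very differently depending on what
else is audible.  `parloud` implements an annoyance-assessment chain
for combined aircraft and road-traffic noise built on **partial
loudness**, the loudness of a target sound in the presence of a
background, with **binaural inhibition** between the ears.

The chain, end to end:

1. **Loudness model** (`parloud.loudness`, `parloud.temporal`) — 1/3-octave
   spectra or calibrated binaural audio → excitation patterns on an
   ERB-number (Cam) grid → specific loudness
   `N′ = C[(E·G + A)^α − A^α]` (sones/Cam), partial specific loudness
   of a target under a masker via the masked-threshold casework, and
   per-ear inhibition `INH = 2 / (1 + sech(S_contra/S_ipsi))^P` with
   `P = 1.598`, so a diotic sound is ≈1.5× (not 2×) as loud as a
   monaural one.  Time-varying sounds get instantaneous / short-term /
   long-term loudness traces via asymmetric AGC smoothing; the maximum
   long-term loudness summarises an event.
2. **Equal-loudness matching** (`parloud.matching`) — predicts the level at
   which a flyover heard over road traffic sounds as loud as the same
   flyover in quiet, and simulates the adaptive 1-up/1-down listening
   procedure (5→1 dB steps) that measures it.
3. **Annoyance models** (`parloud.annoyance`) — logistic exposure-response
   curves in reciprocal form `f(x) = 1/(1/L + a·bˣ)`:
   short-term jury rating `= 1/(0.1 + 0.463·0.936^N)` on the 0–10
   ICBEN scale, and long-term `%HA = 1/(0.01 + 0.043·0.97^N)`
   (percent rating ≥ 8).  Plus refitting, %HA bookkeeping, 5-sone
   binning, and indoor-level corrections (−15 dBA aircraft, −15.8 road).
4. **RLS-90 road emission** (`parloud.rls90`) —
   `Lm,E = 37.3 + 10·log₁₀[Q(1 + 0.082P)]` with speed and gradient
   corrections, per-lane receiver levels and energetic lane combination.
5. **Annoyance mapping** (`parloud.mapping`, `parloud.gridio`) — paired
   aircraft/road LAeq rasters (ESRI ASCII, 10 m cells) → per-cell
   partial-loudness triples → %HA layers per source *with the other as
   background*, exposing the masking asymmetry that ordinary noise
   maps hide.
6. **Synthetic study conditions** (`parloud.synth`) — template source
   spectra, flyover waveforms, the 85-condition jury design, simulated
   ratings and survey responses, and a toy exposure grid, so the whole
   chain runs with no external data.

## Worked example

```python
from parloud import synth, cell_loudness, long_term_pct_ha

cell = cell_loudness(83.0, 55.0)   # outdoor aircraft / road LAeq, dBA
print(round(cell.aircraft_partial, 1), round(cell.road_partial, 4),
      round(cell.total, 1))
print(round(long_term_pct_ha(cell.total), 1))
```

prints

```
30.6 0.0 31.5
37.8
```

— at 83 dBA aircraft over 55 dBA road (indoor 68 / 39.2 dBA), the
road's partial loudness collapses to essentially zero (completely
masked), the aircraft keeps ~97 % of its unmasked loudness, and 37.8 %
of residents at the combined loudness are expected to be highly
annoyed.  The reverse asymmetry never occurs: a weak aircraft over a
strong road remains audible, because the flyover's high-frequency
energy escapes the road's low-frequency masking.

The numbered scripts under `analysis/` walk the full study: stimulus
loudness (`01`), the 3×3 equal-loudness prediction table (`02`,
shifts from +0.7 dB for a 78 dBA flyover over 55 dBA road up to
+10.7 dB for 68 over 75), the simulated jury refit (`03`,
base 0.936, R² ≈ 0.999), the simulated survey refit (`04`), RLS-90
road levels (`05`) and the annoyance map (`06`).  Each writes its
tables under `results/`.

A `parloud` CLI wraps the same steps:

```sh
parloud loudness --spectrum spec.csv --level 68
parloud match --ref 68,73,78 --bg-levels 55,65,75 --out table.csv
parloud fit --ratings jury.csv --kind short_term
parloud map --aircraft a.asc --road r.asc --out-dir maps/
parloud --seed 7 simulate --out-dir fixtures/
```

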