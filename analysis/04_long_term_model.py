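#!/usr/bin/env python
"""Simulate the resident survey over the toy grid and refit the
long-term %HA model.

Receivers on the synthetic exposure grid get indoor levels, partial
loudness, and a Bernoulli highly-annoyed flag from the long-term
curve; records are grouped into 5-sone loudness bins and the logistic
is refit to the per-bin %HA.

Found: binned %HA rises from the ~19 % zero-loudness floor along the
generating curve (refit base ~0.95, R^2 ~0.93 on this tract).  The
curve maximum is weakly identified here because the tract never
drives %HA past ~45; the controlled equal-n recovery simulation in
scripts/acceptance.py pins the coefficients tightly.
"""

from pathlib import Path

from parloud import annoyance as ann
from parloud import synth
from parloud.constants import default_constants

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)
SEED = 20210819


def main():
    c = default_constants()
    # a 600 m x 600 m tract: loud road corridor on one side, flight
    # track on the other, quiet far corner - covers the full loudness
    # range the binning needs
    grid = synth.receiver_grid(
        nx=60, ny=60, road_x_m=40.0, road_source_dba=86.0,
        road_decay_db_per_doubling=7.0, track_y_m=560.0,
        track_altitude_m=100.0, aircraft_source_dba=84.0,
        aircraft_decay_db_per_doubling=11.0,
    )
    survey = synth.simulate_survey(grid, seed=SEED, constants=c)
    survey.to_csv(OUT / "survey_records.csv", index=False)

    print("exposure groups:")
    print(survey.group.value_counts().to_string())

    bins = ann.bin_by_loudness(survey)
    bins.to_csv(OUT / "survey_pct_ha_bins.csv", index=False)
    print("\n%HA per 5-sone loudness bin:")
    print(bins.round(2).to_string(index=False))

    fit = ann.fit_logistic(bins.midpoint_sone, bins.pct_ha,
                           scale_max=100.0, weights=bins.n)
    print(f"\nlong-term refit: maximum {fit.params.L:.1f}, "
          f"scale {fit.params.a:.4f}, base {fit.params.b:.4f}, "
          f"R^2 {fit.r_squared:.3f}")
    with open(OUT / "long_term_fit.txt", "w") as fh:
        fh.write(
            f"L {fit.params.L:.6f}\na {fit.params.a:.6f}\n"
            f"b {fit.params.b:.6f}\nr_squared {fit.r_squared:.6f}\n"
        )


if __name__ == "__main__":
    main()
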