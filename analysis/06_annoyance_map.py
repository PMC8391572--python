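#!/usr/bin/env python
"""Render the per-source %HA annoyance map over the toy exposure grid.

The grid pairs a road line source with an overhead flight track; each
10 m cell gets indoor levels, the partial-loudness triple and three
%HA layers (aircraft-with-road-background, road-with-aircraft-
background, total), written as ESRI ASCII rasters plus a long CSV.

Found: the aircraft %HA layer dips in the road corridor - the same
aircraft exposure annoys less where road noise masks it - while the
road layer is barely dented by the flight track, the background-noise
asymmetry that an energy-based noise map cannot show.
"""

from pathlib import Path

import numpy as np

from parloud import synth
from parloud.constants import default_constants
from parloud.gridio import write_annoyance_grid
from parloud.mapping import annoyance_surface

OUT = Path(__file__).resolve().parents[1] / "results" / "annoyance_map"


def main():
    c = default_constants()
    grid = synth.receiver_grid(nx=40, ny=40)
    surface = annoyance_surface(grid, constants=c)
    written = write_annoyance_grid(OUT, surface)
    for p in written:
        print(f"wrote {p}")

    ha_air = surface.layers["pct_ha_aircraft"]
    ha_road = surface.layers["pct_ha_road"]
    road_col = int(np.argmax(grid.road_dba[0]))
    far_col = int(np.argmin(grid.road_dba[0]))
    print(f"\naircraft %HA on the road axis:   {ha_air[:, road_col].mean():.1f}")
    print(f"aircraft %HA far from the road:  {ha_air[:, far_col].mean():.1f}")
    track_row = int(np.argmax(grid.aircraft_dba[:, 0]))
    far_row = int(np.argmin(grid.aircraft_dba[:, 0]))
    print(f"road %HA under the flight track: {ha_road[track_row].mean():.1f}")
    print(f"road %HA far from the track:     {ha_road[far_row].mean():.1f}")


if __name__ == "__main__":
    main()
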