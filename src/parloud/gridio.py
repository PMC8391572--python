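"""Readers and writers for the package's text formats.

* 1/3-octave spectrum CSV: columns ``freq_hz,level_db_spl`` (header
  required).
* ESRI ASCII grids (``ncols/nrows/xllcorner/yllcorner/cellsize/
  NODATA_value`` header) for exposure and annoyance rasters.
* Long-format raster CSV ``x,y,layer,value``.
* Road-segment CSV mirroring the RLS-90 inputs.
"""

from __future__ import annotations

import io
from pathlib import Path

import numpy as np
import pandas as pd

from .bands import ThirdOctaveSpectrum
from .mapping import AnnoyanceGrid, ExposureGrid
from .rls90 import RoadSegment

__all__ = [
    "read_spectrum_csv",
    "write_spectrum_csv",
    "read_esri_ascii",
    "write_esri_ascii",
    "read_exposure_grids",
    "write_annoyance_grid",
    "read_road_segments_csv",
]

_SEGMENT_COLUMNS = [
    "q_veh_h", "p_trucks_pct", "v_car", "v_truck", "gradient_pct",
    "r_rs", "r_e", "r_da", "r_ga", "r_tb", "k",
]


def read_spectrum_csv(path, sort: bool = True) -> ThirdOctaveSpectrum:
    """Read a band-spectrum CSV (``freq_hz,level_db_spl``).

    With ``sort=True`` rows are ordered by frequency; otherwise
    out-of-order rows are rejected.
    """
    df = pd.read_csv(path)
    missing = {"freq_hz", "level_db_spl"} - set(df.columns)
    if missing:
        raise ValueError(f"spectrum CSV lacks columns: {sorted(missing)}")
    if sort:
        df = df.sort_values("freq_hz")
    return ThirdOctaveSpectrum(
        df["freq_hz"].to_numpy(float), df["level_db_spl"].to_numpy(float)
    )


def write_spectrum_csv(path, spectrum: ThirdOctaveSpectrum) -> None:
    pd.DataFrame(
        {"freq_hz": spectrum.centers_hz, "level_db_spl": spectrum.levels_db}
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------
# ESRI ASCII grids
# ---------------------------------------------------------------------

def read_esri_ascii(path):
    """Read an ESRI ASCII grid; NODATA cells become NaN.

    Returns ``(array, header)`` with the array in map orientation
    (row 0 = northernmost row, as stored).
    """
    header = {}
    lines = Path(path).read_text().splitlines()
    i = 0
    for i, line in enumerate(lines):
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"
        }:
            header[parts[0].lower()] = float(parts[1])
        else:
            break
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise ValueError(f"malformed ESRI ASCII header: missing {key}")
    data = np.loadtxt(io.StringIO("\n".join(lines[i:])))
    data = np.atleast_2d(data)
    if data.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError(
            f"grid body {data.shape} does not match header "
            f"({int(header['nrows'])}, {int(header['ncols'])})"
        )
    nodata = header.get("nodata_value")
    if nodata is not None:
        data = np.where(data == nodata, np.nan, data)
    return data, header


def write_esri_ascii(path, array, xllcorner=0.0, yllcorner=0.0,
                     cellsize=10.0, nodata=-9999.0) -> None:
    """Write a 2-D array as an ESRI ASCII grid; NaN becomes NODATA."""
    a = np.asarray(array, dtype=float)
    body = np.where(np.isnan(a), nodata, a)
    with open(path, "w") as fh:
        fh.write(f"ncols {a.shape[1]}\n")
        fh.write(f"nrows {a.shape[0]}\n")
        fh.write(f"xllcorner {xllcorner:g}\n")
        fh.write(f"yllcorner {yllcorner:g}\n")
        fh.write(f"cellsize {cellsize:g}\n")
        fh.write(f"NODATA_value {nodata:g}\n")
        np.savetxt(fh, body, fmt="%.6f")


def read_exposure_grids(aircraft_path, road_path) -> ExposureGrid:
    """Pair two ESRI ASCII rasters into an ExposureGrid."""
    a, ha = read_esri_ascii(aircraft_path)
    r, hr = read_esri_ascii(road_path)
    if a.shape != r.shape or ha["cellsize"] != hr["cellsize"]:
        raise ValueError("aircraft and road rasters do not align")
    return ExposureGrid(
        origin=(ha["xllcorner"], ha["yllcorner"]),
        cell_m=ha["cellsize"],
        aircraft_dba=np.where(np.isnan(a), -np.inf, a),
        road_dba=np.where(np.isnan(r), -np.inf, r),
    )


def write_annoyance_grid(out_dir, grid: AnnoyanceGrid, long_csv: bool = True) -> list:
    """Write every layer as ESRI ASCII plus one long-format CSV.

    Returns the list of files written.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, layer in grid.layers.items():
        p = out_dir / f"{name}.asc"
        write_esri_ascii(
            p, layer, xllcorner=grid.origin[0], yllcorner=grid.origin[1],
            cellsize=grid.cell_m,
        )
        written.append(p)
    if long_csv:
        ny, nx = grid.shape
        xs = grid.origin[0] + (np.arange(nx) + 0.5) * grid.cell_m
        ys = grid.origin[1] + (np.arange(ny) + 0.5) * grid.cell_m
        rows = []
        for name, layer in grid.layers.items():
            xx, yy = np.meshgrid(xs, ys)
            rows.append(
                pd.DataFrame(
                    {"x": xx.ravel(), "y": yy.ravel(), "layer": name,
                     "value": layer.ravel()}
                )
            )
        p = out_dir / "annoyance_long.csv"
        pd.concat(rows, ignore_index=True).to_csv(p, index=False)
        written.append(p)
    return written


def read_road_segments_csv(path) -> list:
    """Read road segments (one RLS-90 lane per row)."""
    df = pd.read_csv(path)
    missing = set(_SEGMENT_COLUMNS[:2]) - set(df.columns)
    if missing:
        raise ValueError(f"road CSV lacks columns: {sorted(missing)}")
    segments = []
    for row in df.to_dict("records"):
        segments.append(
            RoadSegment(
                q_veh_h=row["q_veh_h"],
                p_trucks_pct=row.get("p_trucks_pct", 0.0),
                v_car=row.get("v_car", 100.0),
                v_truck=row.get("v_truck", 80.0),
                gradient_pct=row.get("gradient_pct", 0.0),
                r_rs=row.get("r_rs", 0.0),
                r_e=row.get("r_e", 0.0),
                r_da=row.get("r_da", 0.0),
                r_ga=row.get("r_ga", 0.0),
                r_tb=row.get("r_tb", 0.0),
                k_intersection=row.get("k", 0.0),
            )
        )
    return segments
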