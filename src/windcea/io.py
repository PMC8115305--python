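"""Plain-text I/O: ESRI ASCII grid rasters, GeoJSON footprints, CSV tables.

Rasters use the ESRI ASCII grid format (``.asc``): a six-line header
(ncols, nrows, xllcorner, yllcorner, cellsize, NODATA_value) followed by
row-major values, upper-left first — a text format every GIS reads.  The
CRS tag travels in a sidecar ``.prj.txt`` file since the format itself has
no CRS slot.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from shapely.geometry import mapping

from .grid import GridError, GridSpec


def write_ascii_grid(path, values: np.ndarray, grid: GridSpec, nodata: float = -9999.0) -> None:
    """Write a raster as an ESRI ASCII grid plus CRS sidecar."""
    path = Path(path)
    values = np.asarray(values, dtype=float)
    if values.shape != grid.shape:
        raise GridError(f"raster shape {values.shape} != grid {grid.shape}")
    xll = grid.origin_x
    yll = grid.origin_y - grid.n_rows * grid.cell_size
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.n_cols}\n")
        fh.write(f"nrows {grid.n_rows}\n")
        fh.write(f"xllcorner {xll!r}\n")
        fh.write(f"yllcorner {yll!r}\n")
        fh.write(f"cellsize {grid.cell_size!r}\n")
        fh.write(f"NODATA_value {nodata!r}\n")
        np.savetxt(fh, values, fmt="%.17g")
    path.with_suffix(path.suffix + ".prj.txt").write_text(grid.crs_tag + "\n")


def read_ascii_grid(path, crs_tag: str | None = None) -> tuple[np.ndarray, GridSpec]:
    """Read an ESRI ASCII grid; CRS comes from the sidecar unless given."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        values = np.loadtxt(fh)
    n_rows = int(header["nrows"])
    n_cols = int(header["ncols"])
    values = values.reshape(n_rows, n_cols)
    if crs_tag is None:
        sidecar = path.with_suffix(path.suffix + ".prj.txt")
        crs_tag = sidecar.read_text().strip() if sidecar.exists() else "local-metres"
    grid = GridSpec(
        origin_x=header["xllcorner"],
        origin_y=header["yllcorner"] + n_rows * header["cellsize"],
        cell_size=header["cellsize"],
        n_rows=n_rows,
        n_cols=n_cols,
        crs_tag=crs_tag,
    )
    nodata = header.get("nodata_value")
    if nodata is not None:
        values = np.where(values == nodata, np.nan, values)
    return values, grid


def write_footprints_geojson(path, farms, crs_tag: str | None = None) -> None:
    """Write farm footprints as a GeoJSON FeatureCollection keyed by farm_id."""
    features = [
        {
            "type": "Feature",
            "properties": {"farm_id": f.farm_id, "country": f.country},
            "geometry": mapping(f.footprint),
        }
        for f in farms
    ]
    doc = {"type": "FeatureCollection", "features": features}
    if crs_tag:
        doc["crs_tag"] = crs_tag
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def write_repository_csv(path, farms) -> None:
    """Write the farm attribute table in the repository CSV layout."""
    import pandas as pd

    rows = [
        {
            "farm_id": f.farm_id,
            "country": f.country,
            "name": f.name,
            "capacity_mw": f.capacity_mw,
            "area_km2": f.area_km2,
            "n_turbines": f.n_turbines,
            "operation_start": f.operation_start,
            "status_flag": f.status_flag,
        }
        for f in farms
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_catalogue_csv(path, catalogue) -> None:
    import pandas as pd

    rows = [
        {
            "pressure_id": p.pressure_id,
            "name": p.name,
            "phase": p.phase,
            "weight": p.weight,
            "distance": p.propagation_distance,
            "confidence": p.confidence,
        }
        for p in catalogue
    ]
    pd.DataFrame(rows).sort_values(["phase", "pressure_id"]).to_csv(path, index=False)


def write_sensitivity_csv(path, sensitivity) -> None:
    sensitivity.to_frame().drop(columns=["score_final"]).to_csv(path, index=False)


def write_ledger_csv(path, ledger) -> None:
    """Write the contribution ledger deterministically (stable order, fixed fmt)."""
    out = ledger.sort_values(
        ["year", "farm", "phase", "pressure", "component"], ignore_index=True
    )
    out.to_csv(path, index=False, float_format="%.12g")
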