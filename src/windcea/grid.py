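"""Analysis grid: raster geometry, footprint rasterization, hexagonal resampling.

The whole assessment runs on a single regular raster in a planar equal-area
reference (coordinates in metres), so per-cell values have an unambiguous
area interpretation.  Grid indexing follows the usual raster convention:
row-major, 0-based, origin at the upper-left cell corner, half-open cell
intervals (a point on a shared edge belongs to the cell right/below it).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from scipy.spatial import cKDTree
from shapely.geometry.base import BaseGeometry


class GridError(ValueError):
    """Raised for grid/CRS mismatches and invalid grid parameters."""


@dataclass(frozen=True)
class GridSpec:
    """Geometry of the shared analysis raster.

    Parameters
    ----------
    origin_x, origin_y
        Coordinates (metres) of the upper-left corner of cell (0, 0).
        y decreases with increasing row index.
    cell_size
        Cell edge length in metres; cell area is ``cell_size**2``.
    n_rows, n_cols
        Raster shape.
    crs_tag
        Identifier of the planar equal-area reference all layers share.
        Compared as an opaque string; no reprojection is performed.
    """

    origin_x: float
    origin_y: float
    cell_size: float
    n_rows: int
    n_cols: int
    crs_tag: str = "local-metres"

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise GridError("cell_size must be positive")
        if self.n_rows < 1 or self.n_cols < 1:
            raise GridError("grid must have at least one row and column")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def cell_area_km2(self) -> float:
        return (self.cell_size / 1000.0) ** 2

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the raster extent."""
        return (
            self.origin_x,
            self.origin_y - self.n_rows * self.cell_size,
            self.origin_x + self.n_cols * self.cell_size,
            self.origin_y,
        )

    def cell_bounds(self, row: int, col: int) -> tuple[float, float, float, float]:
        cs = self.cell_size
        x0 = self.origin_x + col * cs
        y1 = self.origin_y - row * cs
        return (x0, y1 - cs, x0 + cs, y1)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Arrays (n_rows, n_cols) of cell-center x and y coordinates."""
        cs = self.cell_size
        xs = self.origin_x + (np.arange(self.n_cols) + 0.5) * cs
        ys = self.origin_y - (np.arange(self.n_rows) + 0.5) * cs
        return np.meshgrid(xs, ys)


@dataclass
class ActivityRaster:
    """Per-cell coverage fraction of active farm footprints for one (year, phase)."""

    grid: GridSpec
    year: int
    phase: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise GridError(
                f"activity raster shape {self.values.shape} != grid {self.grid.shape}"
            )
        if np.any(self.values < -1e-12) or np.any(self.values > 1 + 1e-12):
            raise GridError("coverage fractions must lie in [0, 1]")

    @property
    def total_area_km2(self) -> float:
        return float(self.values.sum()) * self.grid.cell_area_km2


def coverage_fraction(geometry: BaseGeometry, grid: GridSpec) -> np.ndarray:
    """Exact per-cell coverage fraction of ``geometry`` on ``grid``.

    Uses exact polygon/cell intersection areas (not centroid membership),
    so the rasterized mass equals the clipped polygon area to floating
    precision.  Parts of the geometry outside the grid extent are clipped
    with a warning.
    """
    out = np.zeros(grid.shape, dtype=float)
    if geometry is None or geometry.is_empty:
        return out
    xmin, ymin, xmax, ymax = grid.bounds
    gxmin, gymin, gxmax, gymax = geometry.bounds
    if gxmin < xmin or gymin < ymin or gxmax > xmax or gymax > ymax:
        warnings.warn(
            "footprint extends outside the grid extent and was clipped",
            stacklevel=2,
        )
    cs = grid.cell_size
    c0 = max(0, int(np.floor((gxmin - xmin) / cs)))
    c1 = min(grid.n_cols, int(np.ceil((gxmax - xmin) / cs)))
    r0 = max(0, int(np.floor((ymax - gymax) / cs)))
    r1 = min(grid.n_rows, int(np.ceil((ymax - gymin) / cs)))
    if c0 >= c1 or r0 >= r1:
        return out
    rows, cols = np.mgrid[r0:r1, c0:c1]
    rows = rows.ravel()
    cols = cols.ravel()
    boxes = shapely.box(
        xmin + cols * cs,
        ymax - (rows + 1) * cs,
        xmin + (cols + 1) * cs,
        ymax - rows * cs,
    )
    areas = shapely.area(shapely.intersection(boxes, geometry))
    out[rows, cols] = areas / (cs * cs)
    return out


def rasterize_footprints(
    farms,
    grid: GridSpec,
    year: int,
    phase: str,
    schedules=None,
) -> ActivityRaster:
    """Rasterize the union of footprints of farms active in (year, phase).

    ``farms`` is an iterable of records with ``footprint`` geometry; if
    ``schedules`` (mapping farm_id -> PhaseSchedule) is given, only farms
    whose status in ``year`` equals ``phase`` are burned in.  Overlapping
    footprints are unioned first, so fractions never exceed 1.
    """
    from .repository import status_in_year  # local import, avoids cycle

    geoms = []
    for farm in farms:
        crs = getattr(farm, "crs_tag", None)
        if crs is not None and crs != grid.crs_tag:
            raise GridError(
                f"farm {farm.farm_id!r} CRS {crs!r} does not match grid {grid.crs_tag!r}"
            )
        if schedules is not None:
            if status_in_year(schedules[farm.farm_id], year) != phase:
                continue
        geoms.append(farm.footprint)
    if not geoms:
        return ActivityRaster(grid, year, phase, np.zeros(grid.shape))
    union = shapely.union_all(geoms)
    return ActivityRaster(grid, year, phase, coverage_fraction(union, grid))


def hex_centroids(grid: GridSpec, spacing: float) -> np.ndarray:
    """Centroids of a flat hexagonal lattice covering the grid extent.

    ``spacing`` is the distance between neighbouring centroids within a
    lattice row; rows are ``spacing * sqrt(3)/2`` apart with alternate rows
    offset by half a spacing, the standard hex-packing used for choropleth
    resampling.
    """
    xmin, ymin, xmax, ymax = grid.bounds
    dy = spacing * np.sqrt(3.0) / 2.0
    pts = []
    row = 0
    y = ymax
    while y > ymin - dy:
        xoff = (spacing / 2.0) if (row % 2) else 0.0
        x = xmin + xoff
        while x < xmax + spacing:
            pts.append((x, y))
            x += spacing
        y -= dy
        row += 1
    return np.asarray(pts)


def resample_to_hex(
    values: np.ndarray,
    grid: GridSpec,
    centroid_spacing: float = 10_000.0,
) -> pd.DataFrame:
    """Resample a raster onto a hexagonal lattice by nearest-centroid binning.

    Every source cell is assigned to exactly one hexagon (the nearest lattice
    centroid to the cell center), and hexagon values are the sums of assigned
    cell values, so total mass is conserved exactly.  Returns a DataFrame with
    columns ``hex_id, x, y, value`` (only occupied hexagons).
    """
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise GridError("raster contains non-finite values")
    centroids = hex_centroids(grid, centroid_spacing)
    cx, cy = grid.cell_centers()
    tree = cKDTree(centroids)
    _, idx = tree.query(np.column_stack([cx.ravel(), cy.ravel()]))
    sums = np.bincount(idx, weights=values.ravel(), minlength=len(centroids))
    occupied = np.flatnonzero(np.bincount(idx, minlength=len(centroids)) > 0)
    return pd.DataFrame(
        {
            "hex_id": occupied,
            "x": centroids[occupied, 0],
            "y": centroids[occupied, 1],
            "value": sums[occupied],
        }
    )


def classify_scores(
    values: np.ndarray,
    n_classes: int = 5,
    scheme: str = "quantile",
    breaks=None,
) -> tuple[np.ndarray, dict]:
    """Group scores into ordered classes 1..n_classes for choropleth display.

    ``scheme`` is ``"quantile"`` (default), ``"equal_interval"``, or
    ``"manual"`` with explicit ascending ``breaks`` (interior cut points).
    The mapping is monotone: a higher score never gets a lower class.
    Constant input collapses to a single class 1.  Returns (classes,
    metadata) where metadata records the scheme and cut points actually used.
    """
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise GridError("scores contain non-finite values")
    if np.any(values < 0):
        raise GridError("scores must be nonnegative")
    flat = values.ravel()
    if breaks is not None:
        scheme = "manual"
        cuts = np.asarray(breaks, dtype=float)
    elif flat.max() == flat.min():
        classes = np.ones(values.shape, dtype=int)
        return classes, {"scheme": scheme, "breaks": [], "n_classes": 1}
    elif scheme == "quantile":
        qs = np.linspace(0, 1, n_classes + 1)[1:-1]
        cuts = np.quantile(flat, qs)
    elif scheme == "equal_interval":
        cuts = np.linspace(flat.min(), flat.max(), n_classes + 1)[1:-1]
    else:
        raise GridError(f"unknown classification scheme {scheme!r}")
    classes = (np.searchsorted(cuts, values, side="right") + 1).astype(int)
    return classes, {
        "scheme": scheme,
        "breaks": [float(c) for c in np.atleast_1d(cuts)],
        "n_classes": int(classes.max(initial=1)),
    }
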