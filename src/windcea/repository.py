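"""Offshore wind farm repository: records, lifecycle scheduling, timelines.

Each farm carries the attributes of the geo-spatial OWF repository (code
name, country, name, capacity in MW, area, turbine count, operation start
year, status flag) plus a polygon footprint in a planar equal-area
reference.  The lifecycle model converts capacity into phase durations:
construction takes ``days_per_mw`` (default 1.06) days per installed MW,
operation lasts a fixed span (default 20 years), and decommissioning takes
a fixed fraction (default 0.5) of the construction time.  Durations in days
are rounded up to whole calendar years; construction is anchored backwards
so that it ends the year before operation begins.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import json
import numpy as np
import pandas as pd
import shapely
from shapely.geometry import shape
from shapely.geometry.base import BaseGeometry
from shapely.validation import make_valid

logger = logging.getLogger(__name__)

PHASES = ("construction", "operation", "decommissioning")

STATUS_FLAGS = (
    "consent-authorised",
    "authorised",
    "pre-construction",
    "under-construction",
    "fully-commissioned",
)


class ValidationError(ValueError):
    """Raised when a farm record or schedule violates its invariants."""


class SchedulingError(ValueError):
    """Raised when a farm cannot be scheduled (e.g. missing start year)."""


@dataclass
class FarmRecord:
    """One offshore wind farm with its repository attributes and footprint."""

    farm_id: str
    country: str
    name: str
    capacity_mw: float
    area_km2: float
    n_turbines: int
    operation_start: int | None
    footprint: BaseGeometry
    status_flag: str = "fully-commissioned"
    installation_days: float | None = None  # explicit override of the d/MW rule
    crs_tag: str | None = None

    def validate(self) -> None:
        if not self.farm_id:
            raise ValidationError("farm_id must be non-empty")
        if not self.capacity_mw > 0:
            raise ValidationError(
                f"farm {self.farm_id!r}: capacity must be > 0 MW, got {self.capacity_mw}"
            )
        if self.area_km2 < 0:
            raise ValidationError(f"farm {self.farm_id!r}: area must be >= 0")
        if self.n_turbines < 1:
            raise ValidationError(f"farm {self.farm_id!r}: needs at least 1 turbine")
        if self.operation_start is not None and not (1991 <= self.operation_start <= 2050):
            raise ValidationError(
                f"farm {self.farm_id!r}: operation_start {self.operation_start} "
                "outside [1991, 2050]"
            )
        if self.footprint is None or self.footprint.is_empty:
            raise ValidationError(f"farm {self.farm_id!r}: empty footprint")
        if not self.footprint.is_valid:
            raise ValidationError(f"farm {self.farm_id!r}: invalid footprint geometry")
        if self.status_flag not in STATUS_FLAGS:
            raise ValidationError(
                f"farm {self.farm_id!r}: unknown status flag {self.status_flag!r}"
            )


@dataclass(frozen=True)
class SchedulingRules:
    """Phase-duration parameters of the lifecycle model."""

    days_per_mw: float = 1.06
    operation_span_years: int = 20
    decommissioning_fraction: float = 0.5


@dataclass(frozen=True)
class PhaseSchedule:
    """Half-open year intervals [start, end) for the three lifecycle phases."""

    construction_days: float
    construction_years: tuple[int, int]
    operation_years: tuple[int, int]
    decommissioning_days: float
    decommissioning_years: tuple[int, int]

    def __post_init__(self) -> None:
        if self.construction_years[1] != self.operation_years[0]:
            raise ValidationError("construction must end when operation starts")
        if self.operation_years[1] != self.decommissioning_years[0]:
            raise ValidationError("operation must end when decommissioning starts")
        for lo, hi in (
            self.construction_years,
            self.operation_years,
            self.decommissioning_years,
        ):
            if hi <= lo:
                raise ValidationError("phase intervals must be non-empty")


def _years_for(days: float) -> int:
    """Whole calendar years occupied by an activity of the given duration."""
    return max(1, math.ceil(days / 365.0))


def schedule_phases(farm: FarmRecord, rules: SchedulingRules | None = None) -> PhaseSchedule:
    """Derive a farm's phase schedule from its capacity and operation start.

    Construction duration is ``days_per_mw * capacity`` unless the record
    carries an explicit ``installation_days`` attribute, which takes
    precedence (the discrepancy against the rule is logged).  Durations are
    converted to whole calendar years with ``ceil(days/365)`` (minimum one
    year per phase); construction ends the year before operation starts.
    """
    rules = rules or SchedulingRules()
    if not farm.capacity_mw > 0:
        raise ValidationError(
            f"farm {farm.farm_id!r}: capacity must be positive to schedule"
        )
    if farm.operation_start is None:
        raise SchedulingError(
            f"farm {farm.farm_id!r}: operation start year unknown, cannot schedule"
        )
    formula_days = rules.days_per_mw * farm.capacity_mw
    if farm.installation_days is not None:
        construction_days = float(farm.installation_days)
        if abs(construction_days - formula_days) > 0.5:
            logger.info(
                "farm %s: repository installation time %.0f d overrides the "
                "%.2f d/MW rule (%.0f d)",
                farm.farm_id, construction_days, rules.days_per_mw, formula_days,
            )
    else:
        construction_days = formula_days
    decommissioning_days = rules.decommissioning_fraction * construction_days
    c_years = _years_for(construction_days)
    d_years = _years_for(decommissioning_days)
    op0 = int(farm.operation_start)
    op1 = op0 + rules.operation_span_years
    return PhaseSchedule(
        construction_days=construction_days,
        construction_years=(op0 - c_years, op0),
        operation_years=(op0, op1),
        decommissioning_days=decommissioning_days,
        decommissioning_years=(op1, op1 + d_years),
    )


def status_in_year(schedule: PhaseSchedule, year: int) -> str:
    """Phase label of a scheduled farm in a calendar year.

    Returns one of ``construction, operation, decommissioning`` or ``none``;
    intervals are half-open so every year has exactly one label.
    """
    if schedule.construction_years[0] <= year < schedule.construction_years[1]:
        return "construction"
    if schedule.operation_years[0] <= year < schedule.operation_years[1]:
        return "operation"
    if schedule.decommissioning_years[0] <= year < schedule.decommissioning_years[1]:
        return "decommissioning"
    return "none"


@dataclass
class Repository:
    """A validated collection of farms with their schedules."""

    farms: list[FarmRecord]
    exclusions: list[dict] = field(default_factory=list)
    rules: SchedulingRules = field(default_factory=SchedulingRules)
    schedules: dict[str, PhaseSchedule] = field(init=False)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for farm in self.farms:
            farm.validate()
            if farm.farm_id in seen:
                raise ValidationError(f"duplicate farm_id {farm.farm_id!r}")
            seen.add(farm.farm_id)
        self.schedules = {f.farm_id: schedule_phases(f, self.rules) for f in self.farms}

    def __iter__(self):
        return iter(self.farms)

    def __len__(self) -> int:
        return len(self.farms)

    @property
    def countries(self) -> list[str]:
        return sorted({f.country for f in self.farms})


def _read_geometries(geometry_path) -> dict[str, BaseGeometry]:
    """Read footprint polygons keyed by farm_id from a GeoJSON file."""
    with open(geometry_path) as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise ValidationError("geometry file must be a GeoJSON FeatureCollection")
    geoms: dict[str, BaseGeometry] = {}
    for feat in doc.get("features", []):
        props = feat.get("properties") or {}
        fid = props.get("farm_id")
        if fid is None:
            continue
        geoms[str(fid)] = shape(feat["geometry"])
    return geoms


def load_repository(
    tabular_path,
    geometry_path,
    rules: SchedulingRules | None = None,
    crs_tag: str | None = None,
) -> Repository:
    """Load and join the farm attribute table (CSV) with footprints (GeoJSON).

    Every attribute row must join to exactly one footprint by ``farm_id``.
    Rows that cannot be used (missing footprint, unknown operation start,
    irreparable geometry) are reported in the repository's exclusion list,
    never silently dropped; invalid geometries are repaired with
    ``make_valid`` when the repair preserves a polygonal result.
    """
    table = pd.read_csv(tabular_path)
    required = {"farm_id", "country", "name", "capacity_mw", "area_km2",
                "n_turbines", "operation_start", "status_flag"}
    missing = required - set(table.columns)
    if missing:
        raise ValidationError(f"attribute table missing columns: {sorted(missing)}")
    geoms = _read_geometries(geometry_path)

    ids = table["farm_id"].astype(str)
    dupes = ids[ids.duplicated()].unique().tolist()
    if dupes:
        raise ValidationError(f"duplicate farm_id in attribute table: {dupes}")

    farms: list[FarmRecord] = []
    exclusions: list[dict] = []
    for _, row in table.iterrows():
        fid = str(row["farm_id"])
        geom = geoms.get(fid)
        if geom is None:
            exclusions.append({"farm_id": fid, "reason": "no footprint geometry"})
            continue
        if not geom.is_valid:
            repaired = make_valid(geom)
            if repaired.is_empty or repaired.geom_type not in (
                "Polygon", "MultiPolygon", "GeometryCollection",
            ):
                exclusions.append({"farm_id": fid, "reason": "irreparable geometry"})
                continue
            logger.warning("farm %s: invalid footprint repaired", fid)
            geom = repaired
        op_start = row["operation_start"]
        if pd.isna(op_start):
            exclusions.append(
                {"farm_id": fid, "reason": "operation start year unknown"}
            )
            continue
        inst = row.get("installation_days") if "installation_days" in table.columns else None
        farms.append(
            FarmRecord(
                farm_id=fid,
                country=str(row["country"]),
                name=str(row["name"]),
                capacity_mw=float(row["capacity_mw"]),
                area_km2=float(row["area_km2"]),
                n_turbines=int(row["n_turbines"]),
                operation_start=int(op_start),
                footprint=geom,
                status_flag=str(row["status_flag"]),
                installation_days=None if pd.isna(inst) or inst is None else float(inst),
                crs_tag=crs_tag,
            )
        )
    for ex in exclusions:
        logger.warning("excluded farm %s: %s", ex["farm_id"], ex["reason"])
    return Repository(farms=farms, exclusions=exclusions, rules=rules or SchedulingRules())


def timeline_summary(repo: Repository, years: range | None = None) -> pd.DataFrame:
    """Per-year totals of area (km²) and capacity (GW) by lifecycle phase.

    Uses the repository attribute areas (not rasterized footprints), so the
    summary is exact and additive over farms.  Returns a tidy DataFrame with
    columns ``year, phase, area_km2, capacity_gw`` covering either the given
    year range or every active year in the repository.
    """
    if years is None:
        if not repo.farms:
            return pd.DataFrame(columns=["year", "phase", "area_km2", "capacity_gw"])
        lo = min(s.construction_years[0] for s in repo.schedules.values())
        hi = max(s.decommissioning_years[1] for s in repo.schedules.values())
        years = range(lo, hi)
    rows = []
    for year in years:
        totals = {p: np.zeros(2) for p in PHASES}
        for farm in repo.farms:
            phase = status_in_year(repo.schedules[farm.farm_id], year)
            if phase != "none":
                totals[phase] += (farm.area_km2, farm.capacity_mw / 1000.0)
        for phase in PHASES:
            rows.append(
                {
                    "year": year,
                    "phase": phase,
                    "area_km2": totals[phase][0],
                    "capacity_gw": totals[phase][1],
                }
            )
    return pd.DataFrame(rows)
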