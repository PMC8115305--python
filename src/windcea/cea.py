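"""Cumulative effects engine.

Per cell c and year t, the cumulative effect score is

    CEA_t(c) = sum_k d_k(c) * sum_j s(P_j, E_k) * eff_j(c)
    eff_j(c) = sum_i w_{phase(i,t), j} * [U_i * K_j](c)

where U_i is farm i's activity raster (footprint coverage fraction), K_j the
unit-sum Gaussian kernel of pressure j's propagation distance, w the
phase-specific pressure weight, s the receptor sensitivity and d_k the
receptor distribution.  Totals over the assessment window accumulate
yearly scores, CEA(c) = sum_t CEA_t(c), and every reported percentage is
that raw score times 100 over the grand total.

Alongside the per-cell rasters the engine keeps an additive contribution
ledger at (year, farm, country, phase, pressure, component) granularity;
the ledger — not the rasters — is the source of truth for every marginal
decomposition, which makes all percentage tables mutually consistent by
construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .components import ComponentLayer, SensitivityMatrix
from .grid import GridSpec, coverage_fraction
from .pressures import Kernel, PressureCatalogue, build_kernel, propagate
from .repository import Repository, status_in_year

logger = logging.getLogger(__name__)

LEDGER_AXES = ("year", "farm", "country", "phase", "pressure", "component")


class CEAError(ValueError):
    """Raised for inconsistent CEA inputs or empty results."""


@dataclass
class CEAResult:
    """Raw and normalized cumulative effect scores with their ledger."""

    grid: GridSpec
    years: tuple[int, int]  # inclusive window [first, last]
    yearly_maps: dict[int, np.ndarray]
    ledger: pd.DataFrame  # columns LEDGER_AXES + "score"

    @property
    def total_map(self) -> np.ndarray:
        total = np.zeros(self.grid.shape)
        for m in self.yearly_maps.values():
            total += m
        return total

    @property
    def grand_total(self) -> float:
        return float(self.ledger["score"].sum())

    def normalized_ledger(self) -> pd.DataFrame:
        total = self.grand_total
        if total <= 0:
            raise CEAError("no impact computed: grand total is zero")
        out = self.ledger.copy()
        out["share_pct"] = out["score"] * 100.0 / total
        return out

    def normalized_total_map(self) -> np.ndarray:
        total = self.grand_total
        if total <= 0:
            raise CEAError("no impact computed: grand total is zero")
        return self.total_map * 100.0 / total


def compute_year(
    year: int,
    activities: dict[tuple[str, str], np.ndarray],
    catalogue: PressureCatalogue,
    kernels: dict[float, Kernel],
    layers: dict[str, ComponentLayer],
    sensitivity: SensitivityMatrix,
    grid: GridSpec,
    countries: dict[str, str] | None = None,
    _propagated_cache: dict | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """One year of the assessment: per-cell scores plus ledger entries.

    ``activities`` maps (farm_id, phase) to that farm's activity raster for
    this year (one phase per farm).  Every pressure of an active phase must
    have a kernel for its propagation distance.  Returns the per-cell map
    and a tidy ledger frame whose scores sum exactly to the map total.
    """
    cell_map = np.zeros(grid.shape)
    records: list[dict] = []
    cache = _propagated_cache if _propagated_cache is not None else {}
    for (farm_id, phase), activity in activities.items():
        pressures = catalogue.for_phase(phase)
        for pressure in pressures:
            if pressure.weight == 0.0:
                continue
            kernel = kernels.get(pressure.propagation_distance)
            if kernel is None:
                raise CEAError(
                    f"no kernel built for pressure {pressure.pressure_id!r} "
                    f"(distance {pressure.propagation_distance} m)"
                )
            ckey = (farm_id, phase, pressure.propagation_distance)
            if ckey not in cache:
                cache[ckey] = propagate(activity, kernel)
            surface = pressure.weight * cache[ckey]
            for cid, layer in layers.items():
                s = sensitivity.score(pressure.pressure_id, cid)
                if s == 0.0:
                    continue
                contrib = s * layer.values * surface
                score = float(contrib.sum())
                if score == 0.0:
                    continue
                cell_map += contrib
                records.append(
                    {
                        "year": year,
                        "farm": farm_id,
                        "country": countries.get(farm_id, "?") if countries else "?",
                        "phase": phase,
                        "pressure": pressure.pressure_id,
                        "component": cid,
                        "score": score,
                    }
                )
    ledger = pd.DataFrame(records, columns=[*LEDGER_AXES, "score"])
    return cell_map, ledger


def aggregate_timeline(
    per_year: dict[int, tuple[np.ndarray, pd.DataFrame]],
    grid: GridSpec,
) -> CEAResult:
    """Accumulate contiguous yearly results into a windowed total.

    Years must be contiguous; any gap is reported.  The per-cell total is
    the exact sum of the yearly maps.
    """
    if not per_year:
        raise CEAError("no yearly results to aggregate")
    years = sorted(per_year)
    gaps = [y for y in range(years[0], years[-1] + 1) if y not in per_year]
    if gaps:
        raise CEAError(f"missing years in timeline: {gaps}")
    ledgers = [per_year[y][1] for y in years]
    ledger = pd.concat([l for l in ledgers if not l.empty], ignore_index=True) \
        if any(not l.empty for l in ledgers) else ledgers[0]
    return CEAResult(
        grid=grid,
        years=(years[0], years[-1]),
        yearly_maps={y: per_year[y][0] for y in years},
        ledger=ledger,
    )


def run_cea(
    repo: Repository,
    grid: GridSpec,
    catalogue: PressureCatalogue,
    layers: dict[str, ComponentLayer],
    sensitivity: SensitivityMatrix,
    years: range = range(1999, 2051),
) -> CEAResult:
    """Run the full assessment window over a scheduled repository.

    Footprint rasters and propagated pressure surfaces are static within a
    phase, so they are computed once per (farm, phase, distance) and reused
    across the years of that phase.
    """
    kernels = {d: build_kernel(d, grid.cell_size) for d in catalogue.distances()}
    footprints = {
        f.farm_id: coverage_fraction(f.footprint, grid) for f in repo.farms
    }
    countries = {f.farm_id: f.country for f in repo.farms}
    cache: dict = {}
    per_year: dict[int, tuple[np.ndarray, pd.DataFrame]] = {}
    year_cache: dict[frozenset, tuple[np.ndarray, pd.DataFrame]] = {}
    for year in years:
        activities = {}
        for farm in repo.farms:
            phase = status_in_year(repo.schedules[farm.farm_id], year)
            if phase != "none":
                activities[(farm.farm_id, phase)] = footprints[farm.farm_id]
        key = frozenset(activities)
        if key in year_cache:
            cell_map, ledger_t = year_cache[key]
            ledger = ledger_t.copy()
            ledger["year"] = year
            per_year[year] = (cell_map, ledger)
        else:
            cell_map, ledger = compute_year(
                year, activities, catalogue, kernels, layers, sensitivity,
                grid, countries, _propagated_cache=cache,
            )
            year_cache[key] = (cell_map, ledger)
            per_year[year] = (cell_map, ledger)
    return aggregate_timeline(per_year, grid)


def normalize(result: CEAResult) -> pd.DataFrame:
    """Normalized ledger: each contribution as % of the grand total."""
    return result.normalized_ledger()


def decompose(result: CEAResult, axis) -> pd.DataFrame:
    """Marginal (or cross-tabulated) percentage contribution along ledger axes.

    ``axis`` is one of ``year, phase, country, farm, pressure, component``
    or a list of two of them (cross-tabulation, e.g. pressure x component).
    Percentages are re-derived from the ledger and sum to 100.
    """
    axes = [axis] if isinstance(axis, str) else list(axis)
    for a in axes:
        if a not in LEDGER_AXES:
            raise CEAError(f"unknown decomposition axis {a!r}")
    norm = result.normalized_ledger()
    grouped = norm.groupby(axes, sort=True)["share_pct"].sum()
    return grouped.reset_index()


@dataclass
class ScenarioProjection:
    """Forward projection of CEA contributions from capacity growth.

    Each GW installed in year y contributes the fitted mean construction
    score per GW in year y, the mean yearly operation score per GW for the
    following ``operation_span`` years, and the mean decommissioning score
    per GW in the year after operation ends.
    """

    growth_rate: float
    target_capacity_gw: float
    operation_span: int
    mean_cea_per_gw: dict[str, float]  # per phase, per GW-year
    capacity_path: pd.DataFrame  # year, installed_gw (cumulative)
    contributions: pd.DataFrame  # year, phase, score, source in {observed, projected}


def fitted_cea_per_gw(result: CEAResult, repo: Repository) -> dict[str, float]:
    """Mean raw CEA score per GW per phase-year, fitted from a result.

    For each phase, the total ledger score of that phase divided by the sum
    over farms of (capacity in GW) x (years the farm spends in the phase).
    """
    phase_totals = result.ledger.groupby("phase")["score"].sum()
    gw_years = {p: 0.0 for p in ("construction", "operation", "decommissioning")}
    for farm in repo.farms:
        sched = repo.schedules[farm.farm_id]
        gw = farm.capacity_mw / 1000.0
        gw_years["construction"] += gw * (
            sched.construction_years[1] - sched.construction_years[0]
        )
        gw_years["operation"] += gw * (
            sched.operation_years[1] - sched.operation_years[0]
        )
        gw_years["decommissioning"] += gw * (
            sched.decommissioning_years[1] - sched.decommissioning_years[0]
        )
    return {
        p: float(phase_totals.get(p, 0.0)) / gw_years[p] if gw_years[p] > 0 else 0.0
        for p in gw_years
    }


def project_scenario(
    result: CEAResult,
    repo: Repository,
    growth_rate: float = 0.33,
    target_capacity_gw: float = 212.0,
    operation_span: int = 20,
    horizon: int = 2050,
) -> ScenarioProjection:
    """Project contributions of capacity added beyond the observed window.

    Installed capacity grows at ``growth_rate`` per year from the last
    observed operation start, capped so the cumulative total reaches
    ``target_capacity_gw`` by ``horizon``.  The projection is deliberately
    spatial-free: added capacity contributes through the fitted mean score
    per GW of each phase, not through new footprints, because projected
    scores depend strongly on where future farms would actually sit.
    """
    observed_gw = sum(f.capacity_mw for f in repo.farms) / 1000.0
    if target_capacity_gw < observed_gw:
        raise CEAError(
            f"scenario target {target_capacity_gw} GW below observed "
            f"{observed_gw:.2f} GW"
        )
    rates = fitted_cea_per_gw(result, repo)
    last_installed = max(s.operation_years[0] for s in repo.schedules.values())

    # cumulative capacity path: compound growth capped at the target
    path_rows = []
    capacity = observed_gw
    additions: dict[int, float] = {}
    for year in range(last_installed, horizon + 1):
        if year > last_installed:
            grown = min(capacity * (1.0 + growth_rate), target_capacity_gw)
            additions[year] = grown - capacity
            capacity = grown
        path_rows.append({"year": year, "installed_gw": capacity})
    capacity_path = pd.DataFrame(path_rows)

    observed = (
        result.ledger.groupby(["year", "phase"])["score"].sum().reset_index()
    )
    observed["source"] = "observed"
    proj: dict[tuple[int, str], float] = {}
    for year, gw in additions.items():
        if gw <= 0:
            continue
        proj[(year, "construction")] = proj.get((year, "construction"), 0.0) + (
            gw * rates["construction"]
        )
        for t in range(year + 1, min(year + 1 + operation_span, horizon + 1)):
            proj[(t, "operation")] = proj.get((t, "operation"), 0.0) + (
                gw * rates["operation"]
            )
        t_dec = year + 1 + operation_span
        if t_dec <= horizon:
            proj[(t_dec, "decommissioning")] = proj.get(
                (t_dec, "decommissioning"), 0.0
            ) + gw * rates["decommissioning"]
    projected = pd.DataFrame(
        [
            {"year": y, "phase": p, "score": s, "source": "projected"}
            for (y, p), s in sorted(proj.items())
        ],
        columns=["year", "phase", "score", "source"],
    )
    contributions = pd.concat([observed, projected], ignore_index=True)
    return ScenarioProjection(
        growth_rate=growth_rate,
        target_capacity_gw=target_capacity_gw,
        operation_span=operation_span,
        mean_cea_per_gw=rates,
        capacity_path=capacity_path,
        contributions=contributions,
    )
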