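"""End-to-end pipeline: declarative config, staged execution, provenance.

A run loads the repository and scorecards, schedules every farm, rasterizes
footprints, propagates pressures, accumulates the cumulative effect scores
over the assessment window, normalizes and decomposes them, resamples the
total onto the hexagonal mapping lattice, and (optionally) runs the
scenario projection and the per-phase uncertainty analysis.  A JSON
manifest records the config hash, seed, stage timings and input checksums
so any run can be reproduced and audited.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as wio
from .cea import decompose, project_scenario, run_cea
from .grid import GridSpec, classify_scores, resample_to_hex
from .pressures import load_pressure_catalogue
from .components import load_components, load_sensitivity_table
from .repository import SchedulingRules, load_repository
from .sensitivity import PhaseBundle, run_phase_sa

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Raised when a run configuration cannot be executed."""


@dataclass
class RunConfig:
    """Declarative description of one assessment run.

    All printed constants of the assessment are defaults here — 1.06
    construction days per MW, 20 operation years, decommissioning at half
    the construction time, 10 km hexagon spacing, 1999–2050 window, 5600
    sensitivity-analysis runs — never hard-coded in computation paths.
    """

    repository_csv: str = ""
    footprints_geojson: str = ""
    catalogue_csv: str = ""
    sensitivity_csv: str = ""
    component_dir: str = ""
    output_dir: str = "windcea_run"
    grid: dict = field(default_factory=dict)
    year_start: int = 1999
    year_end: int = 2050
    days_per_mw: float = 1.06
    operation_span_years: int = 20
    decommissioning_fraction: float = 0.5
    hex_spacing_m: float = 10_000.0
    scenario_growth_rate: float = 0.33
    scenario_target_gw: float = 212.0
    sa_budget: int = 5600
    run_scenario: bool = True
    run_sa: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        canon = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def validate_config(config: RunConfig) -> list[tuple[str, str]]:
    """Check a config; returns (level, message) findings, never raises."""
    findings: list[tuple[str, str]] = []
    if config.year_end < config.year_start:
        findings.append(("error", "year range is empty (end before start)"))
    for label, p in (
        ("repository_csv", config.repository_csv),
        ("footprints_geojson", config.footprints_geojson),
        ("catalogue_csv", config.catalogue_csv),
        ("sensitivity_csv", config.sensitivity_csv),
    ):
        if p and not Path(p).exists():
            findings.append(("error", f"{label} path does not exist: {p}"))
    if config.days_per_mw != 1.06:
        findings.append(
            ("warning", f"days_per_mw={config.days_per_mw} deviates from the "
             "standard 1.06 d/MW construction rule")
        )
    if config.operation_span_years != 20:
        findings.append(
            ("warning", f"operation span {config.operation_span_years} y "
             "deviates from the standard 20-year lifetime")
        )
    if config.decommissioning_fraction != 0.5:
        findings.append(
            ("warning", "decommissioning fraction deviates from the standard 0.5")
        )
    if config.sa_budget < 1 and config.run_sa:
        findings.append(("error", "sa_budget must be positive"))
    return findings


def _checksum(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def _grid_from_config(config: RunConfig) -> GridSpec:
    g = dict(config.grid)
    if not g:
        raise ConfigError("config must provide grid parameters")
    return GridSpec(**g)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in order, writing outputs and a JSON manifest."""
    findings = validate_config(config)
    errors = [m for lvl, m in findings if lvl == "error"]
    if errors:
        raise ConfigError("; ".join(errors))
    for lvl, msg in findings:
        logger.warning("config: %s", msg)

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "config": asdict(config),
        "inputs": {},
        "stages": [],
        "complete": False,
    }
    stage_t0 = time.perf_counter()

    def stage_done(name: str) -> None:
        nonlocal stage_t0
        now = time.perf_counter()
        manifest["stages"].append({"stage": name, "seconds": round(now - stage_t0, 4)})
        stage_t0 = now

    def fail(stage: str, exc: Exception):
        manifest["stages"].append({"stage": stage, "error": str(exc)})
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise ConfigError(f"stage {stage!r} failed: {exc}") from exc

    grid = _grid_from_config(config)
    rules = SchedulingRules(
        days_per_mw=config.days_per_mw,
        operation_span_years=config.operation_span_years,
        decommissioning_fraction=config.decommissioning_fraction,
    )

    try:
        for key in ("repository_csv", "footprints_geojson", "catalogue_csv",
                    "sensitivity_csv"):
            p = getattr(config, key)
            if p:
                manifest["inputs"][key] = _checksum(p)
        repo = load_repository(
            config.repository_csv, config.footprints_geojson,
            rules=rules, crs_tag=grid.crs_tag,
        )
    except Exception as exc:  # noqa: BLE001 - abort with stage name
        fail("load", exc)
    stage_done("load")

    try:
        catalogue = load_pressure_catalogue(config.catalogue_csv)
        sensitivity = load_sensitivity_table(config.sensitivity_csv)
        comp_dir = Path(config.component_dir)
        sources = {}
        for asc in sorted(comp_dir.glob("*.asc")):
            cid = asc.stem
            values, cgrid = wio.read_ascii_grid(asc, crs_tag=grid.crs_tag)
            if cgrid.shape != grid.shape:
                raise ConfigError(
                    f"component {cid!r} grid {cgrid.shape} != run grid {grid.shape}"
                )
            meta_path = asc.with_suffix(".meta.json")
            meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
            sources[cid] = {
                "category": meta.get("category", "fish"),
                "kind": meta.get("kind", "density"),
                "values": np.nan_to_num(values),
            }
        if not sources:
            raise ConfigError(f"no component layers (*.asc) in {comp_dir}")
        layers = load_components(sources, grid)
    except Exception as exc:  # noqa: BLE001
        fail("scorecards", exc)
    stage_done("scorecards")

    years = range(config.year_start, config.year_end + 1)
    try:
        result = run_cea(repo, grid, catalogue, layers, sensitivity, years)
    except Exception as exc:  # noqa: BLE001
        fail("cea", exc)
    stage_done("cea")

    wio.write_ascii_grid(out / "cea_total.asc", result.total_map, grid)
    wio.write_ledger_csv(out / "ledger.csv", result.ledger)
    stage_done("rasters")

    norm = result.normalized_ledger()
    norm_path = out / "ledger_normalized.csv"
    wio.write_ledger_csv(norm_path, norm)
    stage_done("normalize")

    for axis in ("year", "phase", "country", "farm", "pressure", "component"):
        decompose(result, axis).to_csv(
            out / f"contribution_by_{axis}.csv", index=False, float_format="%.12g"
        )
    decompose(result, ["pressure", "component"]).to_csv(
        out / "contribution_pressure_x_component.csv", index=False,
        float_format="%.12g",
    )
    stage_done("decompose")

    from .repository import timeline_summary

    timeline_summary(repo, years).to_csv(
        out / "timeline.csv", index=False, float_format="%.12g"
    )
    stage_done("timeline")

    hexes = resample_to_hex(result.normalized_total_map(), grid, config.hex_spacing_m)
    classes, class_meta = classify_scores(hexes["value"].to_numpy())
    hexes = hexes.assign(cea_class=classes)
    hexes.to_csv(out / "hexmap.csv", index=False, float_format="%.12g")
    (out / "hexmap_classes.json").write_text(json.dumps(class_meta, indent=1))
    stage_done("hexmap")

    if config.run_scenario:
        try:
            scenario = project_scenario(
                result, repo,
                growth_rate=config.scenario_growth_rate,
                target_capacity_gw=config.scenario_target_gw,
                operation_span=config.operation_span_years,
                horizon=config.year_end,
            )
        except Exception as exc:  # noqa: BLE001
            fail("scenario", exc)
        scenario.contributions.to_csv(
            out / "scenario_contributions.csv", index=False, float_format="%.12g"
        )
        scenario.capacity_path.to_csv(
            out / "scenario_capacity.csv", index=False, float_format="%.12g"
        )
    stage_done("scenario")

    if config.run_sa:
        try:
            sa_manifests = {}
            for phase in ("construction", "operation", "decommissioning"):
                pressures = catalogue.for_phase(phase)
                if not pressures:
                    continue
                total_activity = np.zeros(grid.shape)
                from .grid import coverage_fraction

                for farm in repo.farms:
                    total_activity += coverage_fraction(farm.footprint, grid)
                bundle = PhaseBundle(
                    phase=phase, activity=np.clip(total_activity, 0, 1),
                    cell_size=grid.cell_size, pressures=pressures,
                    layers=layers, sensitivity=sensitivity,
                )
                sa_result, sa_manifest = run_phase_sa(
                    bundle, budget=config.sa_budget, seed=config.seed,
                )
                sa_result.table.to_csv(
                    out / f"sa_{phase}.csv", index=False, float_format="%.6g"
                )
                sa_manifests[phase] = sa_manifest
            (out / "sa_manifest.json").write_text(json.dumps(sa_manifests, indent=1))
        except Exception as exc:  # noqa: BLE001
            fail("sensitivity_analysis", exc)
    stage_done("sensitivity_analysis")

    manifest["complete"] = True
    manifest["n_farms"] = len(repo)
    manifest["n_excluded"] = len(repo.exclusions)
    manifest["grand_total"] = result.grand_total
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def write_synthetic_inputs(config_syn, out_dir) -> dict:
    """Materialize a synthetic basin in the file formats the pipeline reads."""
    from .synthetic import generate_basin

    out = Path(out_dir)
    comp_dir = out / "components"
    comp_dir.mkdir(parents=True, exist_ok=True)
    repo, layers, catalogue, sensitivity = generate_basin(config_syn)
    wio.write_repository_csv(out / "repository.csv", repo.farms)
    wio.write_footprints_geojson(
        out / "footprints.geojson", repo.farms, crs_tag=config_syn.grid.crs_tag
    )
    wio.write_catalogue_csv(out / "catalogue.csv", catalogue)
    wio.write_sensitivity_csv(out / "sensitivity.csv", sensitivity)
    for cid, layer in layers.items():
        wio.write_ascii_grid(comp_dir / f"{cid}.asc", layer.values, config_syn.grid)
        (comp_dir / f"{cid}.meta.json").write_text(
            json.dumps({"category": layer.category, "kind": layer.kind})
        )
    g = config_syn.grid
    paths = {
        "repository_csv": str(out / "repository.csv"),
        "footprints_geojson": str(out / "footprints.geojson"),
        "catalogue_csv": str(out / "catalogue.csv"),
        "sensitivity_csv": str(out / "sensitivity.csv"),
        "component_dir": str(comp_dir),
        "grid": {
            "origin_x": g.origin_x, "origin_y": g.origin_y,
            "cell_size": g.cell_size, "n_rows": g.n_rows,
            "n_cols": g.n_cols, "crs_tag": g.crs_tag,
        },
    }
    (out / "run_config.yaml").write_text(yaml.safe_dump(paths))
    return paths
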