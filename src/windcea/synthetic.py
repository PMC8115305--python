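"""Synthetic basin generator.

Builds self-contained inputs with the statistical structure of the real
North Sea data sets, so every pipeline stage runs without downloads:

- a farm repository with rectangular, non-overlapping footprints whose
  area scales with capacity, assigned to longitudinal synthetic EEZ bands;
- receptor layers: patchy binary seabed habitats, smooth nonnegative
  density fields for birds and the mammal (log-Gaussian random fields),
  and heavier-tailed log-normal biomass fields for fish emulating
  catch-per-unit-effort surveys;
- scorecards: an 18-pressure catalogue partitioned over the three
  lifecycle phases, and an 18 x 12 two-source sensitivity table with
  confidence levels.

Everything is driven by one integer seed: the same seed reproduces every
artifact bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from shapely.geometry import box

from .components import ComponentLayer, SensitivityCell, SensitivityMatrix, rescale_layer
from .grid import GridSpec
from .pressures import BUFFER_DISTANCES, Pressure, PressureCatalogue
from .repository import FarmRecord, Repository, SchedulingRules

#: Pressure inventory: 18 stressors partitioned over the lifecycle phases,
#: mirroring the catalogue structure of an offshore wind farm assessment.
PRESSURE_NAMES: dict[str, list[str]] = {
    "construction": [
        "underwater_noise_piling", "habitat_loss", "sedimentation",
        "release_sediment_contaminants", "vessel_collision_risk",
        "visual_disturbance_construction",
    ],
    "operation": [
        "underwater_noise_operational", "electromagnetic_fields",
        "habitat_change_structures", "collision_risk_rotors",
        "barrier_effect", "marine_litter",
    ],
    "decommissioning": [
        "underwater_noise_removal", "habitat_disturbance_removal",
        "resuspension_sediments", "vessel_disturbance_decom",
        "waste_generation", "visual_disturbance_decom",
    ],
}

#: Receptor inventory: 3 seabed habitats, 3 seabirds, 1 mammal, 5 fish.
COMPONENT_SPECS: list[tuple[str, str, str]] = [
    ("A3_infralittoral_rock", "seabed habitat", "presence_absence"),
    ("A4_circalittoral_rock", "seabed habitat", "presence_absence"),
    ("A5_sublittoral_sediment", "seabed habitat", "presence_absence"),
    ("razorbill", "bird", "density"),
    ("fulmar", "bird", "density"),
    ("guillemot", "bird", "density"),
    ("harbour_porpoise", "mammal", "density"),
    ("haddock", "fish", "density"),
    ("sandeel", "fish", "density"),
    ("whiting", "fish", "density"),
    ("saithe", "fish", "density"),
    ("sprat", "fish", "density"),
]

CONFIDENCE_LEVELS = (0.2, 0.4, 0.6, 0.8, 1.0)


@dataclass
class SyntheticBasinConfig:
    """Study conditions for the synthetic basin.

    Defaults follow the real assessment's setup where one is stated —
    10 km analysis cells, 1999–2027 installation window, the 18-pressure /
    12-receptor inventories — and otherwise hold desk-scale values a basin
    of a few hundred kilometres would have.
    """

    grid: GridSpec = field(
        default_factory=lambda: GridSpec(
            origin_x=0.0, origin_y=500_000.0, cell_size=10_000.0,
            n_rows=50, n_cols=50, crs_tag="synthetic-equal-area",
        )
    )
    n_countries: int = 3
    n_farms: int = 15
    capacity_range_mw: tuple[float, float] = (60.0, 1200.0)
    operation_start_range: tuple[int, int] = (2001, 2028)
    area_density_km2_per_mw: float = 0.23
    smoothness_cells: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_farms < 1 or self.n_countries < 1:
            raise ValueError("need at least one farm and one country")
        if self.capacity_range_mw[0] <= 0:
            raise ValueError("capacities must be positive")


def _country_labels(n: int) -> list[str]:
    return [f"EEZ_{chr(ord('A') + i)}" for i in range(n)]


def generate_farms(config: SyntheticBasinConfig) -> Repository:
    """Generate a validated synthetic farm repository.

    Footprints are axis-aligned squares with area ``density * capacity``
    km², placed without overlap inside the longitudinal band of their
    country; placement failure after bounded retries means the grid is too
    small for the requested farm count.
    """
    rng = np.random.default_rng(config.seed)
    xmin, ymin, xmax, ymax = config.grid.bounds
    band_w = (xmax - xmin) / config.n_countries
    countries = _country_labels(config.n_countries)
    farms: list[FarmRecord] = []
    placed: list = []
    for i in range(config.n_farms):
        capacity = float(
            rng.uniform(*config.capacity_range_mw)
        )
        area_km2 = config.area_density_km2_per_mw * capacity
        side = math.sqrt(area_km2) * 1000.0  # metres
        country_idx = i % config.n_countries
        bx0 = xmin + country_idx * band_w
        bx1 = bx0 + band_w
        footprint = None
        for _ in range(200):
            x0 = rng.uniform(bx0, max(bx0, bx1 - side))
            y0 = rng.uniform(ymin, max(ymin, ymax - side))
            cand = box(x0, y0, x0 + side, y0 + side)
            if all(not cand.intersects(g) for g in placed):
                footprint = cand
                break
        if footprint is None:
            raise ValueError(
                f"grid too small to place {config.n_farms} farms without overlap"
            )
        placed.append(footprint)
        op_start = int(rng.integers(*config.operation_start_range))
        farms.append(
            FarmRecord(
                farm_id=f"{countries[country_idx]}_{i + 1}",
                country=countries[country_idx],
                name=f"Synthetic wind farm {i + 1}",
                capacity_mw=capacity,
                area_km2=area_km2,
                n_turbines=max(1, int(round(capacity / 8.0))),
                operation_start=op_start,
                footprint=footprint,
                status_flag="fully-commissioned",
                crs_tag=config.grid.crs_tag,
            )
        )
    return Repository(farms=farms, rules=SchedulingRules())


def _smooth_field(rng: np.random.Generator, shape, corr_cells: float) -> np.ndarray:
    """Zero-mean Gaussian random field with the given correlation length."""
    noise = rng.standard_normal(shape)
    field_ = gaussian_filter(noise, sigma=corr_cells, mode="reflect")
    std = field_.std()
    return field_ / std if std > 0 else field_


def generate_component_layers(
    config: SyntheticBasinConfig,
) -> dict[str, ComponentLayer]:
    """Generate the 12 receptor layers on the config grid.

    Habitats threshold a smooth field into contiguous binary patches
    covering roughly a third of the basin each.  Bird/mammal densities are
    exponentiated smooth fields (mildly skewed, like modelled animal
    densities).  Fish layers draw heavier-tailed log-normal biomass and go
    through the standard log[x + 1] + min–max rescaling.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    shape = config.grid.shape
    layers: dict[str, ComponentLayer] = {}
    for cid, category, kind in COMPONENT_SPECS:
        f = _smooth_field(rng, shape, config.smoothness_cells)
        if kind == "presence_absence":
            values = (f > np.quantile(f, 0.65)).astype(float)
        elif category in ("bird", "mammal"):
            dens = np.exp(0.8 * f)
            v = dens - dens.min()
            values = v / v.max() if v.max() > 0 else v
        else:  # fish: log-normal biomass, heavier tail, standard transform
            biomass = np.exp(1.5 * f + 0.5 * rng.standard_normal(shape))
            values = rescale_layer(biomass)
        layers[cid] = ComponentLayer(
            component_id=cid, category=category, kind=kind,
            grid=config.grid, values=values,
        )
    return layers


def generate_scorecards(
    config: SyntheticBasinConfig,
) -> tuple[PressureCatalogue, SensitivityMatrix]:
    """Generate the pressure catalogue and the 18 x 12 sensitivity table.

    Weights are drawn on [1, 5] (half-point steps), propagation distances
    from the five kernel buffer classes, confidences from the 0.2–1 ladder.
    Sensitivity rows carry separate literature and expert scores; the final
    score applies the precautionary aggregation rule.
    """
    from .components import aggregate_score

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    pressures: list[Pressure] = []
    for phase, names in PRESSURE_NAMES.items():
        for name in names:
            pressures.append(
                Pressure(
                    pressure_id=name,
                    name=name.replace("_", " "),
                    phase=phase,
                    weight=float(rng.integers(2, 11)) / 2.0,
                    propagation_distance=float(rng.choice(BUFFER_DISTANCES)),
                    confidence=float(rng.choice(CONFIDENCE_LEVELS)),
                )
            )
    catalogue = PressureCatalogue(pressures)

    cells: list[SensitivityCell] = []
    for pr in pressures:
        for cid, _, _ in COMPONENT_SPECS:
            lit = float(rng.integers(0, 6))
            expert = float(np.clip(lit + rng.integers(-2, 3), 0, 5))
            cells.append(
                SensitivityCell(
                    pressure_id=pr.pressure_id,
                    component_id=cid,
                    score_literature=lit,
                    score_expert=expert,
                    confidence=float(rng.choice(CONFIDENCE_LEVELS)),
                    score_final=aggregate_score(lit, expert),
                )
            )
    return catalogue, SensitivityMatrix(cells)


def generate_basin(config: SyntheticBasinConfig | None = None):
    """Convenience: full synthetic scenario (repository, layers, scorecards)."""
    config = config or SyntheticBasinConfig()
    repo = generate_farms(config)
    layers = generate_component_layers(config)
    catalogue, sensitivity = generate_scorecards(config)
    return repo, layers, catalogue, sensitivity


def analytic_fixture():
    """A complete scenario whose CEA is computable by hand.

    One farm occupying exactly one 1 km cell, one pressure per phase with
    sub-cell propagation distance (identity kernels) and weights
    (5, 2, 3) for (construction, operation, decommissioning), one uniform
    receptor with d = 1 everywhere and sensitivity 4 to every pressure.
    With a (1, 20, 1)-year schedule the raw yearly score in the farm cell
    is w_phase * 4, so phase totals are (20, 160, 12) and normalized phase
    shares (10.4167%, 83.3333%, 6.25%).
    """
    grid = GridSpec(
        origin_x=0.0, origin_y=5_000.0, cell_size=1_000.0,
        n_rows=5, n_cols=5, crs_tag="synthetic-equal-area",
    )
    footprint = box(2_000.0, 2_000.0, 3_000.0, 3_000.0)  # exactly cell (2, 2)
    farm = FarmRecord(
        farm_id="FIX_1", country="EEZ_A", name="Analytic fixture farm",
        capacity_mw=100.0, area_km2=1.0, n_turbines=10,
        operation_start=2010, footprint=footprint,
        crs_tag=grid.crs_tag,
    )
    repo = Repository(farms=[farm])
    weights = {"construction": 5.0, "operation": 2.0, "decommissioning": 3.0}
    pressures = [
        Pressure(
            pressure_id=f"{phase}_pressure", name=f"{phase} pressure",
            phase=phase, weight=w, propagation_distance=500.0, confidence=1.0,
        )
        for phase, w in weights.items()
    ]
    catalogue = PressureCatalogue(pressures)
    layers = {
        "uniform_receptor": ComponentLayer(
            component_id="uniform_receptor", category="seabed habitat",
            kind="presence_absence", grid=grid, values=np.ones(grid.shape),
        )
    }
    cells = [
        SensitivityCell(
            pressure_id=p.pressure_id, component_id="uniform_receptor",
            score_literature=4.0, score_expert=4.0, confidence=1.0,
            score_final=4.0,
        )
        for p in pressures
    ]
    sensitivity = SensitivityMatrix(cells)
    expected = {
        "raw_phase_totals": {
            "construction": 20.0, "operation": 160.0, "decommissioning": 12.0,
        },
        "phase_shares_pct": {
            "construction": 100.0 * 20.0 / 192.0,
            "operation": 100.0 * 160.0 / 192.0,
            "decommissioning": 100.0 * 12.0 / 192.0,
        },
    }
    return grid, repo, layers, catalogue, sensitivity, expected
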