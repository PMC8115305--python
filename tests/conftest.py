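import numpy as np
import pytest
from shapely.geometry import box

from windcea import (
    ComponentLayer,
    FarmRecord,
    GridSpec,
    Pressure,
    PressureCatalogue,
    Repository,
    SensitivityCell,
    SensitivityMatrix,
)


@pytest.fixture
def unit_grid():
    """5x5 grid of 1 km cells, origin at (0, 5000)."""
    return GridSpec(origin_x=0.0, origin_y=5_000.0, cell_size=1_000.0,
                    n_rows=5, n_cols=5, crs_tag="test-metres")


@pytest.fixture
def one_cell_farm(unit_grid):
    """A farm whose footprint exactly covers grid cell (2, 2)."""
    return FarmRecord(
        farm_id="T_1", country="EEZ_A", name="test farm",
        capacity_mw=100.0, area_km2=1.0, n_turbines=10,
        operation_start=2020, footprint=box(2_000, 2_000, 3_000, 3_000),
        crs_tag=unit_grid.crs_tag,
    )


@pytest.fixture
def small_repo(one_cell_farm):
    return Repository(farms=[one_cell_farm])


@pytest.fixture
def uniform_layer(unit_grid):
    return {
        "uniform": ComponentLayer(
            component_id="uniform", category="seabed habitat",
            kind="presence_absence", grid=unit_grid,
            values=np.ones(unit_grid.shape),
        )
    }


def make_catalogue(entries):
    """entries: iterable of (pressure_id, phase, weight, distance, confidence)."""
    return PressureCatalogue([
        Pressure(pressure_id=pid, name=pid, phase=phase, weight=w,
                 propagation_distance=dist, confidence=conf)
        for pid, phase, w, dist, conf in entries
    ])


def make_sensitivity(scores, confidence=1.0):
    """scores: mapping (pressure_id, component_id) -> final score."""
    return SensitivityMatrix([
        SensitivityCell(pressure_id=p, component_id=c, score_literature=s,
                        score_expert=s, confidence=confidence, score_final=s)
        for (p, c), s in scores.items()
    ])


@pytest.fixture
def repository_files(tmp_path):
    """Write a 3-farm attribute CSV + footprint GeoJSON pair; return paths."""
    import json

    csv = tmp_path / "repo.csv"
    csv.write_text(
        "farm_id,country,name,capacity_mw,area_km2,n_turbines,"
        "operation_start,status_flag\n"
        "A_1,EEZ_A,Alpha,100,15,12,2010,fully-commissioned\n"
        "A_2,EEZ_A,Beta,500,75,50,2015,fully-commissioned\n"
        "B_1,EEZ_B,Gamma,1000,150,80,2020,under-construction\n"
    )
    feats = []
    for i, fid in enumerate(["A_1", "A_2", "B_1"]):
        x0 = i * 20_000.0
        feats.append({
            "type": "Feature",
            "properties": {"farm_id": fid},
            "geometry": {
                "type": "Polygon",
                "coordinates": [[[x0, 0], [x0 + 10_000, 0],
                                 [x0 + 10_000, 10_000], [x0, 10_000], [x0, 0]]],
            },
        })
    geojson = tmp_path / "repo.geojson"
    geojson.write_text(json.dumps({"type": "FeatureCollection", "features": feats}))
    return csv, geojson
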