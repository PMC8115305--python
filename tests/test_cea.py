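import numpy as np
import pandas as pd
import pytest

from windcea import (
    ComponentLayer,
    GridSpec,
    aggregate_timeline,
    build_kernel,
    compute_year,
    decompose,
    project_scenario,
    run_cea,
)
from windcea.cea import CEAError, CEAResult, fitted_cea_per_gw
from windcea.pressures import Kernel

from conftest import make_catalogue, make_sensitivity
from test_pressures import brute_force_convolve

IDENTITY = Kernel(radius=500.0, sigma=500 / 3, window=np.ones((1, 1)))


def triple_loop_reference(activities, weights, distances, sens, layers, cell_size):
    """Independent accumulation: explicit loops over farms, pressures,
    components and cells, with brute-force convolution."""
    some_layer = next(iter(layers.values()))
    total = np.zeros_like(some_layer)
    for (farm, phase), activity in activities.items():
        for j, w in weights.get(phase, {}).items():
            window = build_kernel(distances[j], cell_size).window
            prop = brute_force_convolve(activity, window)
            for k, d in layers.items():
                s = sens.get((j, k), 0.0)
                for idx in np.ndindex(total.shape):
                    total[idx] += d[idx] * s * w * prop[idx]
    return total


class TestComputeYear:
    def test_single_cell_closed_form(self, unit_grid, uniform_layer):
        cat = make_catalogue([("noise", "construction", 5.0, 1_000.0, 1.0)])
        sens = make_sensitivity({("noise", "uniform"): 5.0})
        activity = np.zeros(unit_grid.shape)
        activity[2, 2] = 1.0
        cell_map, ledger = compute_year(
            2020, {("T_1", "construction"): activity}, cat,
            {1_000.0: IDENTITY}, uniform_layer, sens, unit_grid,
        )
        assert cell_map[2, 2] == pytest.approx(25.0)
        assert cell_map.sum() == pytest.approx(25.0)
        assert ledger.score.sum() == pytest.approx(25.0)

    def test_absent_receptor_annihilates(self, unit_grid):
        cat = make_catalogue([("noise", "construction", 5.0, 1_000.0, 1.0)])
        sens = make_sensitivity({("noise", "empty"): 5.0})
        layers = {
            "empty": ComponentLayer(
                component_id="empty", category="fish", kind="density",
                grid=unit_grid, values=np.zeros(unit_grid.shape),
            )
        }
        activity = np.ones(unit_grid.shape)
        cell_map, ledger = compute_year(
            2020, {("T_1", "construction"): activity}, cat,
            {1_000.0: IDENTITY}, layers, sens, unit_grid,
        )
        assert np.all(cell_map == 0.0)
        assert ledger.empty

    def test_missing_kernel_raises(self, unit_grid, uniform_layer):
        cat = make_catalogue([("noise", "construction", 5.0, 5_000.0, 1.0)])
        sens = make_sensitivity({("noise", "uniform"): 5.0})
        with pytest.raises(CEAError, match="kernel"):
            compute_year(
                2020, {("T_1", "construction"): np.ones(unit_grid.shape)},
                cat, {}, uniform_layer, sens, unit_grid,
            )

    def test_matches_triple_loop_oracle(self):
        """8x8 grid, 2 farms, 3 pressures, 2 components, random scores."""
        rng = np.random.default_rng(99)
        grid = GridSpec(origin_x=0, origin_y=8_000, cell_size=1_000,
                        n_rows=8, n_cols=8)
        activities = {
            ("F_1", "construction"): rng.random(grid.shape),
            ("F_2", "construction"): rng.random(grid.shape),
        }
        weights = {"construction": {"p1": 1.5, "p2": 4.0, "p3": 2.5}}
        distances = {"p1": 1_000.0, "p2": 2_000.0, "p3": 3_000.0}
        scores = {(j, k): float(rng.integers(0, 6))
                  for j in distances for k in ("c1", "c2")}
        layer_vals = {"c1": rng.random(grid.shape), "c2": rng.random(grid.shape)}
        layers = {
            k: ComponentLayer(component_id=k, category="fish", kind="density",
                              grid=grid, values=v)
            for k, v in layer_vals.items()
        }
        cat = make_catalogue([
            (j, "construction", weights["construction"][j], distances[j], 1.0)
            for j in distances
        ])
        sens = make_sensitivity(scores)
        kernels = {d: build_kernel(d, grid.cell_size) for d in distances.values()}
        cell_map, ledger = compute_year(
            2020, activities, cat, kernels, layers, sens, grid,
        )
        expected = triple_loop_reference(
            activities, weights, distances, scores, layer_vals, grid.cell_size
        )
        np.testing.assert_allclose(cell_map, expected, rtol=1e-9, atol=1e-12)
        assert ledger.score.sum() == pytest.approx(cell_map.sum(), rel=1e-9)


class TestAggregateAndNormalize:
    def _result(self, unit_grid, yearly_cell_values):
        per_year = {}
        for year, val in yearly_cell_values.items():
            cell_map = np.zeros(unit_grid.shape)
            cell_map[0, 0] = val
            ledger = pd.DataFrame(
                [{"year": year, "farm": "T_1", "country": "A",
                  "phase": "operation", "pressure": "noise",
                  "component": "uniform", "score": val}]
            ) if val else pd.DataFrame(
                columns=["year", "farm", "country", "phase", "pressure",
                         "component", "score"]
            )
            per_year[year] = (cell_map, ledger)
        return aggregate_timeline(per_year, unit_grid)

    def test_yearly_sum_identity(self, unit_grid):
        result = self._result(unit_grid, {2000: 2.0, 2001: 0.0, 2002: 3.0})
        assert result.total_map[0, 0] == pytest.approx(5.0)

    def test_missing_year_reported(self, unit_grid):
        with pytest.raises(CEAError, match="2001"):
            self._result(unit_grid, {2000: 1.0, 2002: 1.0})

    def test_normalized_shares(self, unit_grid):
        result = self._result(unit_grid, {2000: 3.0, 2001: 1.0})
        by_year = decompose(result, "year")
        np.testing.assert_allclose(by_year.share_pct.to_numpy(), [75.0, 25.0])

    def test_all_marginals_sum_to_100(self, small_repo, unit_grid, uniform_layer):
        cat = make_catalogue([
            ("noise", "construction", 4.0, 1_000.0, 1.0),
            ("litter", "operation", 2.0, 2_000.0, 1.0),
            ("removal", "decommissioning", 3.0, 1_000.0, 1.0),
        ])
        sens = make_sensitivity({
            ("noise", "uniform"): 3.0, ("litter", "uniform"): 2.0,
            ("removal", "uniform"): 5.0,
        })
        result = run_cea(small_repo, unit_grid, cat, uniform_layer, sens,
                         years=range(2015, 2045))
        for axis in ("year", "phase", "country", "farm", "pressure", "component"):
            total = decompose(result, axis).share_pct.sum()
            assert total == pytest.approx(100.0, abs=1e-6)
        cross = decompose(result, ["pressure", "component"])
        assert cross.share_pct.sum() == pytest.approx(100.0, abs=1e-6)

    def test_weight_scale_invariance_of_shares(
        self, small_repo, unit_grid, uniform_layer
    ):
        entries = [("noise", "construction", 2.0, 1_000.0, 1.0),
                   ("litter", "operation", 1.0, 1_000.0, 1.0)]
        sens = make_sensitivity({("noise", "uniform"): 3.0,
                                 ("litter", "uniform"): 2.0})
        years = range(2015, 2045)
        res1 = run_cea(small_repo, unit_grid, make_catalogue(entries),
                       uniform_layer, sens, years)
        doubled = [(p, ph, 2 * w, d, c) for p, ph, w, d, c in entries]
        res2 = run_cea(small_repo, unit_grid, make_catalogue(doubled),
                       uniform_layer, sens, years)
        assert res2.grand_total == pytest.approx(2 * res1.grand_total, rel=1e-12)
        a = decompose(res1, "phase").set_index("phase").share_pct
        b = decompose(res2, "phase").set_index("phase").share_pct
        pd.testing.assert_series_equal(a, b)

    def test_zero_total_normalization_rejected(self, unit_grid):
        ledger = pd.DataFrame(columns=["year", "farm", "country", "phase",
                                       "pressure", "component", "score"])
        result = CEAResult(grid=unit_grid, years=(2000, 2000),
                           yearly_maps={2000: np.zeros(unit_grid.shape)},
                           ledger=ledger)
        with pytest.raises(CEAError, match="no impact"):
            result.normalized_ledger()

    def test_unknown_axis_rejected(self, unit_grid):
        result = self._result(unit_grid, {2000: 1.0})
        with pytest.raises(CEAError, match="axis"):
            decompose(result, "species")


class TestDecompositionSymmetries:
    def test_two_identical_farms_split_evenly(self, unit_grid, uniform_layer,
                                              one_cell_farm):
        import copy

        from windcea import Repository

        other = copy.deepcopy(one_cell_farm)
        other.farm_id = "T_2"
        from shapely.geometry import box
        other.footprint = box(0, 4_000, 1_000, 5_000)
        repo = Repository(farms=[one_cell_farm, other])
        # sub-cell distance: identity kernel, so edge truncation cannot
        # break the symmetry between an interior and a corner farm
        cat = make_catalogue([("noise", "operation", 3.0, 500.0, 1.0)])
        sens = make_sensitivity({("noise", "uniform"): 2.0})
        with pytest.warns(UserWarning, match="identity"):
            result = run_cea(repo, unit_grid, cat, uniform_layer, sens,
                             years=range(2015, 2045))
        by_farm = decompose(result, "farm").set_index("farm").share_pct
        assert by_farm["T_1"] == pytest.approx(50.0)
        assert by_farm["T_2"] == pytest.approx(50.0)

    def test_farm_order_permutation_invariance(self, unit_grid, uniform_layer,
                                               one_cell_farm):
        import copy

        from shapely.geometry import box

        from windcea import Repository

        other = copy.deepcopy(one_cell_farm)
        other.farm_id = "T_2"
        other.capacity_mw = 700.0
        other.footprint = box(0, 4_000, 1_000, 5_000)
        cat = make_catalogue([("noise", "operation", 3.0, 2_000.0, 1.0)])
        sens = make_sensitivity({("noise", "uniform"): 2.0})
        years = range(2010, 2045)
        r1 = run_cea(Repository(farms=[one_cell_farm, other]), unit_grid, cat,
                     uniform_layer, sens, years)
        r2 = run_cea(Repository(farms=[other, one_cell_farm]), unit_grid, cat,
                     uniform_layer, sens, years)
        np.testing.assert_allclose(r1.total_map, r2.total_map, rtol=1e-12)
        a = decompose(r1, "farm").sort_values("farm", ignore_index=True)
        b = decompose(r2, "farm").sort_values("farm", ignore_index=True)
        pd.testing.assert_frame_equal(a, b)

    def test_ledger_conserves_raster_mass(self, small_repo, unit_grid,
                                          uniform_layer):
        cat = make_catalogue([("noise", "operation", 3.0, 2_000.0, 1.0)])
        sens = make_sensitivity({("noise", "uniform"): 2.0})
        result = run_cea(small_repo, unit_grid, cat, uniform_layer, sens,
                         years=range(2015, 2045))
        raster_total = sum(m.sum() for m in result.yearly_maps.values())
        assert result.grand_total == pytest.approx(raster_total, rel=1e-9)


class TestScenario:
    def _fitted(self, small_repo, unit_grid, uniform_layer):
        cat = make_catalogue([
            ("noise", "construction", 4.0, 1_000.0, 1.0),
            ("litter", "operation", 2.0, 1_000.0, 1.0),
            ("removal", "decommissioning", 3.0, 1_000.0, 1.0),
        ])
        sens = make_sensitivity({("noise", "uniform"): 3.0,
                                 ("litter", "uniform"): 2.0,
                                 ("removal", "uniform"): 5.0})
        return run_cea(small_repo, unit_grid, cat, uniform_layer, sens,
                       years=range(2015, 2045))

    def test_zero_growth_adds_nothing(self, small_repo, unit_grid, uniform_layer):
        result = self._fitted(small_repo, unit_grid, uniform_layer)
        proj = project_scenario(result, small_repo, growth_rate=0.0,
                                target_capacity_gw=1.0, horizon=2050)
        assert (proj.contributions.source == "projected").sum() == 0

    def test_added_gw_contribution_schedule(self, small_repo, unit_grid,
                                            uniform_layer):
        """1 GW installed in year y: construction score at y, operation for
        the following 20 years, decommissioning the year after."""
        result = self._fitted(small_repo, unit_grid, uniform_layer)
        rates = fitted_cea_per_gw(result, small_repo)
        # enormous growth rate installs (target - observed) GW immediately
        proj = project_scenario(result, small_repo, growth_rate=1e9,
                                target_capacity_gw=1.1, operation_span=20,
                                horizon=2060)
        added = 1.1 - 0.1  # observed farm is 100 MW
        p = proj.contributions[proj.contributions.source == "projected"]
        y = 2021  # last observed operation start 2020 -> growth starts 2021
        con = p[(p.year == y) & (p.phase == "construction")].score.item()
        assert con == pytest.approx(added * rates["construction"])
        ops = p[p.phase == "operation"]
        assert ops.year.min() == y + 1 and ops.year.max() == y + 20
        np.testing.assert_allclose(ops.score, added * rates["operation"])
        dec = p[p.phase == "decommissioning"]
        assert dec.year.item() == y + 21
        assert dec.score.item() == pytest.approx(added * rates["decommissioning"])

    def test_capacity_path_monotone_and_capped(self, small_repo, unit_grid,
                                               uniform_layer):
        result = self._fitted(small_repo, unit_grid, uniform_layer)
        proj = project_scenario(result, small_repo, growth_rate=0.33,
                                target_capacity_gw=5.0, horizon=2050)
        path = proj.capacity_path.installed_gw.to_numpy()
        assert np.all(np.diff(path) >= 0)
        assert path[-1] == pytest.approx(5.0)

    def test_target_below_observed_rejected(self, small_repo, unit_grid,
                                            uniform_layer):
        result = self._fitted(small_repo, unit_grid, uniform_layer)
        with pytest.raises(CEAError, match="below observed"):
            project_scenario(result, small_repo, target_capacity_gw=0.01)
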