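import numpy as np
import pytest

from windcea import (
    PhaseBundle,
    UncertainInput,
    run_phase_sa,
    sample_design,
    total_order_index,
)
from windcea.sensitivity import DesignError

from conftest import make_sensitivity


def _inputs(n, confidence=0.2, base=2.5):
    return [
        UncertainInput(f"x{i}", "effect_function", base, confidence)
        for i in range(n)
    ]


class TestSampleDesign:
    def test_evaluation_count(self):
        design = sample_design(_inputs(5), n_base=800, seed=0)
        assert design.n_evaluations == 5600

    def test_full_confidence_column_is_constant(self):
        inputs = _inputs(2) + [UncertainInput("fixed", "effect_function", 3.0, 1.0)]
        design = sample_design(inputs, n_base=64, seed=0)
        assert np.all(design.A[:, 2] == 3.0)
        assert np.all(design.B[:, 2] == 3.0)

    def test_samples_respect_legal_domain(self):
        inputs = [UncertainInput("edge", "effect_function", 0.5, 0.2)]
        design = sample_design(inputs, n_base=256, seed=1)
        assert design.A.min() >= 0.0 and design.A.max() <= 5.0

    def test_seed_reproducibility(self):
        d1 = sample_design(_inputs(3), n_base=128, seed=42)
        d2 = sample_design(_inputs(3), n_base=128, seed=42)
        np.testing.assert_array_equal(d1.A, d2.A)
        np.testing.assert_array_equal(d1.B, d2.B)

    def test_no_inputs_rejected(self):
        with pytest.raises(DesignError):
            sample_design([], n_base=8, seed=0)


class TestTotalOrderIndex:
    def _evaluate(self, design, f):
        fA = f(design.A)
        fB = f(design.B)
        fAB = np.column_stack([f(design.AB(i)) for i in range(design.p)])
        return fA, fAB, fB

    def test_unperturbed_input_has_exactly_zero_index(self):
        inputs = _inputs(2) + [UncertainInput("fixed", "effect_function", 3.0, 1.0)]
        design = sample_design(inputs, n_base=128, seed=3)
        f = lambda X: X.sum(axis=1) + X[:, 0] * X[:, 1]
        fA, fAB, fB = self._evaluate(design, f)
        res = total_order_index(fA, fAB, fB, inputs=inputs)
        assert res.table.set_index("input_id").ST["fixed"] == 0.0

    def test_single_variable_model(self):
        inputs = _inputs(3)
        design = sample_design(inputs, n_base=1024, seed=5)
        f = lambda X: X[:, 0]
        fA, fAB, fB = self._evaluate(design, f)
        res = total_order_index(fA, fAB, fB, inputs=inputs)
        st = res.table.set_index("input_id").ST
        assert st["x0"] == pytest.approx(1.0, abs=0.02)
        assert st["x1"] == pytest.approx(0.0, abs=0.02)
        assert st["x2"] == pytest.approx(0.0, abs=0.02)

    def test_additive_model_recovers_analytic_indices(self):
        """f = a1 x1 + a2 x2 with independent uniforms: the total order index
        of x_i is a_i^2 s_i^2 / sum(a^2 s^2), from the variance of a sum."""
        a1, a2 = 2.0, 1.0
        inputs = [
            UncertainInput("x1", "effect_function", 2.5, 0.2),  # halfwidth 2.0
            UncertainInput("x2", "effect_function", 2.5, 0.6),  # halfwidth 1.0
        ]
        var = [(hi - lo) ** 2 / 12.0 for lo, hi in
               (i.interval() for i in inputs)]
        expected = np.array([a1**2 * var[0], a2**2 * var[1]])
        expected = expected / expected.sum()
        design = sample_design(inputs, n_base=2000, seed=7)
        f = lambda X: a1 * X[:, 0] + a2 * X[:, 1]
        fA, fAB, fB = self._evaluate(design, f)
        res = total_order_index(fA, fAB, fB, inputs=inputs)
        st = res.table.set_index("input_id").ST
        assert st["x1"] == pytest.approx(expected[0], abs=0.02)
        assert st["x2"] == pytest.approx(expected[1], abs=0.02)
        # additive model: indices sum to 1 (no interactions)
        assert st.sum() == pytest.approx(1.0, abs=0.04)

    def test_ishigami_closed_form(self):
        """Ishigami with a=7, b=0.1: total indices from the closed-form
        variance decomposition, independently derived."""
        a, b = 7.0, 0.1
        inputs = [
            UncertainInput(f"x{i}", "effect_function", 0.0, 1.0,
                           interval_override=(-np.pi, np.pi))
            for i in range(3)
        ]
        design = sample_design(inputs, n_base=1024, seed=11)

        def ishigami(X):
            return (np.sin(X[:, 0]) + a * np.sin(X[:, 1]) ** 2
                    + b * X[:, 2] ** 4 * np.sin(X[:, 0]))

        fA, fAB, fB = self._evaluate(design, ishigami)
        res = total_order_index(fA, fAB, fB, inputs=inputs)
        V = a**2 / 8 + b * np.pi**4 / 5 + b**2 * np.pi**8 / 18 + 0.5
        v13 = 8 * b**2 * np.pi**8 / 225
        st_true = [
            (0.5 * (1 + b * np.pi**4 / 5) ** 2 + v13) / V,
            (a**2 / 8) / V,
            v13 / V,
        ]
        st = res.table.set_index("input_id").ST
        for i in range(3):
            assert st[f"x{i}"] == pytest.approx(st_true[i], abs=0.05)

    def test_zero_variance_reported_degenerate(self):
        inputs = _inputs(2)
        design = sample_design(inputs, n_base=64, seed=0)
        fA = np.full(64, 3.0)
        fAB = np.full((64, 2), 3.0)
        res = total_order_index(fA, fAB, inputs=inputs)
        assert res.degenerate
        assert res.table.ST.isna().all()

    def test_input_order_invariance(self):
        inputs = _inputs(3)
        f = lambda X: X[:, 0] + 2 * X[:, 1] + X[:, 1] * X[:, 2]
        design = sample_design(inputs, n_base=512, seed=9)
        fA, fAB, fB = self._evaluate(design, f)
        st1 = total_order_index(fA, fAB, fB, inputs=inputs).table
        st2 = total_order_index(fA, fAB, fB, inputs=inputs).table
        assert st1.equals(st2)


class TestRunPhaseSA:
    def _bundle(self, unit_grid, uniform_layer, confidences):
        from windcea import Pressure

        pressures = [
            Pressure(pressure_id=f"p{i}", name=f"p{i}", phase="construction",
                     weight=3.0, propagation_distance=500.0, confidence=c)
            for i, c in enumerate(confidences)
        ]
        sens = make_sensitivity(
            {(p.pressure_id, "uniform"): 3.0 for p in pressures}, confidence=1.0
        )
        activity = np.zeros(unit_grid.shape)
        activity[2, 2] = 1.0
        return PhaseBundle(
            phase="construction", activity=activity,
            cell_size=unit_grid.cell_size, pressures=pressures,
            layers=uniform_layer, sensitivity=sens,
        )

    def test_single_perturbed_weight_ranks_first(self, unit_grid, uniform_layer):
        bundle = self._bundle(unit_grid, uniform_layer, [0.2, 1.0, 1.0])
        result, manifest = run_phase_sa(bundle, budget=600, seed=2)
        top = result.table.iloc[0]
        assert top.input_id == "weight:p0"
        assert top.ST == pytest.approx(1.0, abs=0.05)
        fixed = result.table[result.table.input_id == "weight:p1"]
        assert fixed.ST.item() == 0.0

    def test_all_confidences_one_is_degenerate(self, unit_grid, uniform_layer):
        bundle = self._bundle(unit_grid, uniform_layer, [1.0, 1.0])
        result, manifest = run_phase_sa(bundle, budget=100, seed=0)
        assert result.degenerate
        assert "no uncertainty" in manifest["note"]

    def test_budget_met_and_manifest_recorded(self, unit_grid, uniform_layer):
        bundle = self._bundle(unit_grid, uniform_layer, [0.4, 0.6])
        result, manifest = run_phase_sa(bundle, budget=500, seed=4)
        assert manifest["n_evaluations"] >= 500
        assert {i["input_id"] for i in manifest["inputs"]} >= {
            "weight:p0", "distance:p0", "effect:p0->uniform"
        }

    def test_empty_phase_rejected(self, unit_grid, uniform_layer):
        bundle = PhaseBundle(
            phase="operation", activity=np.zeros(unit_grid.shape),
            cell_size=unit_grid.cell_size, pressures=[],
            layers=uniform_layer, sensitivity=make_sensitivity({}),
        )
        with pytest.raises(DesignError, match="operation"):
            run_phase_sa(bundle, budget=100, seed=0)

    def test_ranking_consistent_with_larger_budget(self, unit_grid, uniform_layer):
        """One dominant high-variance input keeps its rank at 10x budget."""
        bundle = self._bundle(unit_grid, uniform_layer, [0.2, 0.8, 0.9])
        small, _ = run_phase_sa(bundle, budget=400, seed=6)
        large, _ = run_phase_sa(bundle, budget=4000, seed=6)
        assert small.table.iloc[0].input_id == large.table.iloc[0].input_id
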