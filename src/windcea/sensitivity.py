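"""Variance-based uncertainty analysis (Total Order Index per input).

Each expert-scored quantity carries a confidence level on [0.2, 1];
the lower the confidence, the wider the interval over which the quantity
is perturbed in randomized model runs.  Inputs fall in two groups: the
pressure-propagation model (weight and distance of each pressure) and the
effect functions (sensitivity score of each pressure-component pair).

The sampling design is Saltelli's radial scheme — a base matrix A, a
resample matrix B, and per-input hybrids AB_i equal to A with column i
taken from B — for a total of ``n_base * (p + 2)`` model evaluations.
Total order indices use the Jansen estimator

    ST_i = mean[(f(A) - f(AB_i))^2] / (2 * Var[f]),

which captures each input's full contribution to output variance including
all its interactions.  Base points are drawn from a scrambled Sobol'
sequence for fast, seed-reproducible convergence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import qmc

SCORE_DOMAIN = (0.0, 5.0)


class DesignError(ValueError):
    """Raised for unusable sampling designs (no inputs, no variance)."""


@dataclass(frozen=True)
class UncertainInput:
    """One perturbable model input with its confidence-driven interval.

    The perturbation half-width is ``(1 - confidence)`` times half the
    score domain width for scores, or times the base value for distances;
    samples are uniform on the interval clipped to the legal domain.
    """

    input_id: str
    group: str  # "pressure_propagation" | "effect_function"
    base_value: float
    confidence: float
    domain: tuple[float, float] = SCORE_DOMAIN
    is_distance: bool = False
    interval_override: tuple[float, float] | None = None

    def interval(self) -> tuple[float, float]:
        if self.interval_override is not None:
            return self.interval_override
        if not 0.2 <= self.confidence <= 1.0:
            raise DesignError(
                f"input {self.input_id!r}: confidence {self.confidence} "
                "outside [0.2, 1]"
            )
        if self.is_distance:
            half = (1.0 - self.confidence) * self.base_value
        else:
            half = (1.0 - self.confidence) * (self.domain[1] - self.domain[0]) / 2.0
        lo = max(self.domain[0], self.base_value - half)
        hi = min(self.domain[1], self.base_value + half)
        return (lo, hi)


@dataclass
class SampleDesign:
    """Saltelli radial design realized on the inputs' intervals."""

    inputs: list[UncertainInput]
    n_base: int
    A: np.ndarray  # (n_base, p)
    B: np.ndarray  # (n_base, p)

    @property
    def p(self) -> int:
        return len(self.inputs)

    @property
    def n_evaluations(self) -> int:
        return self.n_base * (self.p + 2)

    def AB(self, i: int) -> np.ndarray:
        out = self.A.copy()
        out[:, i] = self.B[:, i]
        return out


def sample_design(
    inputs: list[UncertainInput],
    n_base: int,
    seed: int,
) -> SampleDesign:
    """Draw the A/B base matrices for a Saltelli radial design.

    Uses a scrambled Sobol' sequence of dimension 2p split into A and B;
    an input with confidence 1 has a degenerate interval, so its column is
    constant across all matrices and its total order index is exactly 0.
    """
    p = len(inputs)
    if p == 0:
        raise DesignError("no uncertain inputs to sample")
    if n_base < 2:
        raise DesignError("n_base must be at least 2")
    with warnings.catch_warnings():
        # Sobol' balance warning for non-power-of-two n is informational here
        warnings.simplefilter("ignore", UserWarning)
        sampler = qmc.Sobol(d=2 * p, scramble=True, seed=seed)
        unit = sampler.random(n_base)
    lo = np.array([i.interval()[0] for i in inputs])
    hi = np.array([i.interval()[1] for i in inputs])
    A = lo + unit[:, :p] * (hi - lo)
    B = lo + unit[:, p:] * (hi - lo)
    return SampleDesign(inputs=inputs, n_base=n_base, A=A, B=B)


@dataclass
class TotalOrderResult:
    """Estimated total order indices with bootstrap intervals, ranked."""

    phase: str
    table: pd.DataFrame  # input_id, group, ST, ci_low, ci_high, rank
    n_runs: int
    degenerate: bool = False  # True when output variance is zero

    def ranked_ids(self) -> list[str]:
        return self.table.sort_values("rank")["input_id"].tolist()


def total_order_index(
    f_A: np.ndarray,
    f_AB: np.ndarray,
    f_B: np.ndarray | None = None,
    inputs: list[UncertainInput] | None = None,
    phase: str = "",
    n_bootstrap: int = 200,
    seed: int = 0,
) -> TotalOrderResult:
    """Jansen total-order estimate per input from design evaluations.

    ``f_A`` has shape (n_base,), ``f_AB`` shape (n_base, p).  The output
    variance in the denominator pools f(A) and f(B) when the latter is
    given.  Bootstrap intervals resample base points.  Zero output variance
    yields a degenerate result with every index reported as NaN.
    """
    f_A = np.asarray(f_A, dtype=float)
    f_AB = np.asarray(f_AB, dtype=float)
    if f_AB.ndim != 2 or f_AB.shape[0] != f_A.shape[0]:
        raise DesignError("f_AB must have shape (n_base, p)")
    if not (np.all(np.isfinite(f_A)) and np.all(np.isfinite(f_AB))):
        raise DesignError("model outputs contain non-finite values")
    n, p = f_AB.shape
    pooled = f_A if f_B is None else np.concatenate([f_A, np.asarray(f_B, float)])

    def _st(idx: np.ndarray) -> np.ndarray:
        var = np.var(pooled) if f_B is None else np.var(
            np.concatenate([f_A[idx], np.asarray(f_B, float)[idx]])
        )
        d2 = (f_A[idx, None] - f_AB[idx, :]) ** 2
        num = d2.mean(axis=0) / 2.0
        with np.errstate(invalid="ignore", divide="ignore"):
            return num / var

    var_total = float(np.var(pooled))
    ids = [i.input_id for i in inputs] if inputs else [f"x{i}" for i in range(p)]
    groups = [i.group for i in inputs] if inputs else ["?"] * p
    if var_total == 0.0:
        table = pd.DataFrame(
            {
                "input_id": ids,
                "group": groups,
                "ST": np.nan,
                "ci_low": np.nan,
                "ci_high": np.nan,
                "rank": range(1, p + 1),
            }
        )
        return TotalOrderResult(
            phase=phase, table=table, n_runs=n * (p + 2), degenerate=True
        )

    full = np.arange(n)
    st = _st(full)
    rng = np.random.default_rng(seed)
    boots = np.empty((n_bootstrap, p))
    for b in range(n_bootstrap):
        boots[b] = _st(rng.integers(0, n, size=n))
    ci_low = np.nanpercentile(boots, 2.5, axis=0)
    ci_high = np.nanpercentile(boots, 97.5, axis=0)
    order = np.argsort(-st)
    rank = np.empty(p, dtype=int)
    rank[order] = np.arange(1, p + 1)
    table = pd.DataFrame(
        {
            "input_id": ids,
            "group": groups,
            "ST": st,
            "ci_low": ci_low,
            "ci_high": ci_high,
            "rank": rank,
        }
    ).sort_values("rank", ignore_index=True)
    return TotalOrderResult(phase=phase, table=table, n_runs=n * (p + 2))


@dataclass
class PhaseBundle:
    """A fixed, phase-restricted scenario the sensitivity analysis evaluates.

    Holds the total activity raster of one lifecycle phase, the phase's
    pressures, the receptor layers and the sensitivity matrix.  Each model
    evaluation recomputes the scalar total CEA of the bundle under
    perturbed weights, propagation distances, and effect scores.
    """

    phase: str
    activity: np.ndarray
    cell_size: float
    pressures: list  # of Pressure
    layers: dict  # component_id -> ComponentLayer
    sensitivity: object  # SensitivityMatrix
    _layer_sums: dict = field(init=False, default_factory=dict)

    def uncertain_inputs(self) -> list[UncertainInput]:
        inputs: list[UncertainInput] = []
        for pr in self.pressures:
            inputs.append(
                UncertainInput(
                    input_id=f"weight:{pr.pressure_id}",
                    group="pressure_propagation",
                    base_value=pr.weight,
                    confidence=pr.confidence,
                )
            )
            inputs.append(
                UncertainInput(
                    input_id=f"distance:{pr.pressure_id}",
                    group="pressure_propagation",
                    base_value=pr.propagation_distance,
                    confidence=pr.confidence,
                    domain=(self.cell_size / 2.0, 50_000.0 * 2.0),
                    is_distance=True,
                )
            )
            for cid in self.layers:
                base = self.sensitivity.score(pr.pressure_id, cid)
                conf = self.sensitivity.confidence(pr.pressure_id, cid)
                inputs.append(
                    UncertainInput(
                        input_id=f"effect:{pr.pressure_id}->{cid}",
                        group="effect_function",
                        base_value=base,
                        confidence=conf,
                    )
                )
        return inputs

    def evaluate(self, x: np.ndarray, inputs: list[UncertainInput]) -> float:
        from .pressures import build_kernel, propagate

        values = dict(zip((i.input_id for i in inputs), x))
        total = 0.0
        cids = list(self.layers)
        for pr in self.pressures:
            w = values.get(f"weight:{pr.pressure_id}", pr.weight)
            dist = values.get(f"distance:{pr.pressure_id}", pr.propagation_distance)
            surface = propagate(self.activity, build_kernel(dist, self.cell_size))
            for cid in cids:
                s = values.get(
                    f"effect:{pr.pressure_id}->{cid}",
                    self.sensitivity.score(pr.pressure_id, cid),
                )
                if s == 0.0 or w == 0.0:
                    continue
                total += w * s * float((self.layers[cid].values * surface).sum())
        return total


def run_phase_sa(
    bundle: PhaseBundle,
    budget: int = 5600,
    seed: int = 0,
    n_bootstrap: int = 200,
) -> tuple[TotalOrderResult, dict]:
    """Phase-level sensitivity analysis under the requested run budget.

    The number of base samples is sized so that ``n_base * (p + 2)``
    meets or exceeds the budget.  Returns the ranked result and a manifest
    (seed, budget, per-input perturbation intervals) for provenance.
    """
    if not bundle.pressures:
        raise DesignError(f"phase {bundle.phase!r} has no pressures")
    inputs = bundle.uncertain_inputs()
    perturbed = [i for i in inputs if i.interval()[0] < i.interval()[1]]
    manifest = {
        "phase": bundle.phase,
        "seed": int(seed),
        "budget": int(budget),
        "inputs": [
            {
                "input_id": i.input_id,
                "group": i.group,
                "base_value": i.base_value,
                "confidence": i.confidence,
                "interval": list(i.interval()),
            }
            for i in inputs
        ],
    }
    if not perturbed:
        table = pd.DataFrame(
            columns=["input_id", "group", "ST", "ci_low", "ci_high", "rank"]
        )
        manifest["note"] = "no uncertainty: all confidences are 1"
        return (
            TotalOrderResult(phase=bundle.phase, table=table, n_runs=0, degenerate=True),
            manifest,
        )
    p = len(perturbed)
    n_base = max(2, int(np.ceil(budget / (p + 2))))
    design = sample_design(perturbed, n_base, seed)
    f_A = np.array([bundle.evaluate(row, perturbed) for row in design.A])
    f_B = np.array([bundle.evaluate(row, perturbed) for row in design.B])
    f_AB = np.empty((n_base, p))
    for i in range(p):
        ab = design.AB(i)
        f_AB[:, i] = [bundle.evaluate(row, perturbed) for row in ab]
    result = total_order_index(
        f_A, f_AB, f_B, inputs=perturbed, phase=bundle.phase,
        n_bootstrap=n_bootstrap, seed=seed,
    )
    fixed = [i for i in inputs if i not in perturbed]
    if fixed and not result.degenerate:
        # an input with zero perturbation cannot move the output: ST is 0 exactly
        zero_rows = pd.DataFrame(
            {
                "input_id": [i.input_id for i in fixed],
                "group": [i.group for i in fixed],
                "ST": 0.0,
                "ci_low": 0.0,
                "ci_high": 0.0,
                "rank": range(p + 1, p + 1 + len(fixed)),
            }
        )
        result.table = pd.concat([result.table, zero_rows], ignore_index=True)
    manifest["n_base"] = n_base
    manifest["n_evaluations"] = design.n_evaluations
    return result, manifest
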