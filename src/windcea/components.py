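"""Environmental components (receptors) and the pressure-sensitivity matrix.

Receptor layers d(E_k) are gridded distributions on [0, 1]: binary
presence/absence for seabed habitats, continuous rescaled densities for
seabirds, mammals and fish.  Raw density/biomass layers are transformed
with log[x + 1] — damping the dominance of extreme values typical of
count and catch-per-unit-effort data — and then min–max rescaled to the
unit interval so all receptors are compared on one unit-less scale.

Sensitivity scores s(P_j, E_k) on [0, 5] come from two sources (literature
review and expert elicitation) and are merged with a precautionary rule:
sources in modest disagreement take the higher score, sources in strong
disagreement (difference above 2 units) take the mean.  Each score carries
a confidence level on [0.2, 1] used only by the uncertainty analysis.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import GridSpec, GridError, coverage_fraction

logger = logging.getLogger(__name__)

CATEGORIES = ("seabed habitat", "bird", "mammal", "fish")


class ScoreError(ValueError):
    """Raised for out-of-range sensitivity or confidence values."""


@dataclass
class ComponentLayer:
    """One receptor distribution d(E_k) on the shared analysis grid."""

    component_id: str
    category: str
    kind: str  # "presence_absence" | "density"
    grid: GridSpec
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ScoreError(
                f"component {self.component_id!r}: unknown category {self.category!r}"
            )
        if self.kind not in ("presence_absence", "density"):
            raise ScoreError(
                f"component {self.component_id!r}: unknown kind {self.kind!r}"
            )
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise GridError(
                f"component {self.component_id!r} on a mismatched grid: "
                f"{self.values.shape} != {self.grid.shape}"
            )
        if np.any(self.values < 0) or np.any(self.values > 1):
            raise ScoreError(
                f"component {self.component_id!r}: values outside [0, 1]"
            )
        if self.kind == "presence_absence":
            uniq = np.unique(self.values)
            if not np.all(np.isin(uniq, (0.0, 1.0))):
                raise ScoreError(
                    f"component {self.component_id!r}: presence/absence layer "
                    "must be binary"
                )


def rescale_layer(raw: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """log[x + 1] transform followed by min–max rescaling to [0, 1].

    ``mask`` (optional, boolean) marks the study-area cells over which the
    min and max are taken, so land/no-data cells never set the range;
    masked-out cells are returned as 0.  A constant layer rescales to
    all-zero with a warning.
    """
    raw = np.asarray(raw, dtype=float)
    if not np.all(np.isfinite(raw)):
        raise ScoreError("raw layer contains non-finite values")
    neg = np.argwhere(raw < 0)
    if neg.size:
        raise ScoreError(
            f"negative raw value at cell {tuple(int(i) for i in neg[0])}"
        )
    v = np.log1p(raw)
    if mask is None:
        sel = np.ones(raw.shape, dtype=bool)
    else:
        sel = np.asarray(mask, dtype=bool)
    vmin = v[sel].min()
    vmax = v[sel].max()
    out = np.zeros_like(v)
    if vmax == vmin:
        warnings.warn("constant layer rescaled to all-zero", stacklevel=2)
        return out
    out[sel] = (v[sel] - vmin) / (vmax - vmin)
    return out


def aggregate_score(lit: float | None, expert: float | None) -> float:
    """Merge literature and expert scores into a final sensitivity score.

    Strongly disagreeing sources (difference > 2 units) are averaged;
    otherwise the higher score is adopted (precautionary principle — an
    exact difference of 2 also takes the max).  A missing source leaves
    the other score unchanged.
    """
    if lit is None and expert is None:
        raise ScoreError("both scores missing")
    if lit is None:
        lit = expert
    if expert is None:
        expert = lit
    for val, label in ((lit, "literature"), (expert, "expert")):
        if not 0.0 <= val <= 5.0:
            raise ScoreError(f"{label} score {val} outside [0, 5]")
    if abs(lit - expert) > 2.0:
        return (lit + expert) / 2.0
    return max(lit, expert)


@dataclass(frozen=True)
class SensitivityCell:
    pressure_id: str
    component_id: str
    score_literature: float | None
    score_expert: float | None
    confidence: float
    score_final: float

    def __post_init__(self) -> None:
        if not 0.2 <= self.confidence <= 1.0:
            raise ScoreError(
                f"sensitivity ({self.pressure_id}, {self.component_id}): "
                f"confidence {self.confidence} outside [0.2, 1]"
            )


class SensitivityMatrix:
    """Lookup of s(P_j, E_k); pairs without a row score 0 (insensitive)."""

    def __init__(self, cells: list[SensitivityCell]):
        self._cells: dict[tuple[str, str], SensitivityCell] = {}
        for cell in cells:
            key = (cell.pressure_id, cell.component_id)
            if key in self._cells:
                raise ScoreError(f"duplicate sensitivity row for {key}")
            self._cells[key] = cell
        self._warned: set[tuple[str, str]] = set()

    def __len__(self) -> int:
        return len(self._cells)

    def __iter__(self):
        return iter(self._cells.values())

    def score(self, pressure_id: str, component_id: str) -> float:
        cell = self._cells.get((pressure_id, component_id))
        if cell is None:
            key = (pressure_id, component_id)
            if key not in self._warned:
                logger.info(
                    "no sensitivity score for (%s, %s): treated as insensitive",
                    pressure_id, component_id,
                )
                self._warned.add(key)
            return 0.0
        return cell.score_final

    def confidence(self, pressure_id: str, component_id: str) -> float:
        cell = self._cells.get((pressure_id, component_id))
        return cell.confidence if cell is not None else 1.0

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "pressure_id": c.pressure_id,
                "component_id": c.component_id,
                "score_literature": c.score_literature,
                "score_expert": c.score_expert,
                "confidence": c.confidence,
                "score_final": c.score_final,
            }
            for c in sorted(
                self._cells.values(), key=lambda c: (c.pressure_id, c.component_id)
            )
        ]
        return pd.DataFrame(rows)


def load_sensitivity_table(path) -> SensitivityMatrix:
    """Load the sensitivity scorecard (CSV) and aggregate its two sources.

    Expects columns ``pressure_id, component_id, score_literature,
    score_expert, confidence``; an optional precomputed ``score_final``
    column is recomputed and must agree with the aggregation rule.
    """
    table = pd.read_csv(path)
    required = {"pressure_id", "component_id", "score_literature",
                "score_expert", "confidence"}
    missing = required - set(table.columns)
    if missing:
        raise ScoreError(f"sensitivity table missing columns: {sorted(missing)}")
    cells = []
    for idx, row in table.iterrows():
        lit = None if pd.isna(row["score_literature"]) else float(row["score_literature"])
        exp = None if pd.isna(row["score_expert"]) else float(row["score_expert"])
        try:
            final = aggregate_score(lit, exp)
        except ScoreError as exc:
            raise ScoreError(f"sensitivity row {idx}: {exc}") from exc
        cells.append(
            SensitivityCell(
                pressure_id=str(row["pressure_id"]),
                component_id=str(row["component_id"]),
                score_literature=lit,
                score_expert=exp,
                confidence=float(row["confidence"]),
                score_final=final,
            )
        )
    return SensitivityMatrix(cells)


def load_components(
    sources: dict[str, dict],
    grid: GridSpec,
) -> dict[str, ComponentLayer]:
    """Assemble receptor layers on the shared grid from heterogeneous sources.

    ``sources`` maps component_id to a spec dict with keys ``category``,
    ``kind`` and one of:

    - ``values``: a raw array already on the grid (densities get
      ``rescale_layer`` applied unless already spanning [0, 1] exactly);
    - ``polygon``: a shapely geometry burned to a binary presence raster
      (any positive cell coverage counts as presence).
    """
    layers: dict[str, ComponentLayer] = {}
    for cid, spec in sources.items():
        kind = spec["kind"]
        if "polygon" in spec:
            frac = coverage_fraction(spec["polygon"], grid)
            values = (frac > 0).astype(float)
        else:
            values = np.asarray(spec["values"], dtype=float)
            if values.shape != grid.shape:
                raise GridError(
                    f"component {cid!r} on a mismatched grid: "
                    f"{values.shape} != {grid.shape}"
                )
            if kind == "density":
                already_unit = (
                    values.min() == 0.0 and values.max() == 1.0
                    and np.all(values >= 0) and np.all(values <= 1)
                )
                if not already_unit:
                    values = rescale_layer(values, spec.get("mask"))
        layers[cid] = ComponentLayer(
            component_id=cid,
            category=spec["category"],
            kind=kind,
            grid=grid,
            values=values,
        )
    return layers
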