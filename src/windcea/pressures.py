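"""Pressure catalogue and kernel-based pressure propagation.

A pressure is a phase-specific stressor (underwater noise, marine litter,
habitat loss, ...) with a relative weight on [0, 5], an ordinal propagation
distance class, and an expert confidence on [0.2, 1].  Activity rasters are
spread into pressure-intensity surfaces by convolution with a truncated 2D
Gaussian kernel whose buffer radius realises the distance class.

Kernels are unit-sum (mass preserving): enlarging the propagation distance
redistributes a farm's pressure over a wider area without amplifying the
total, which is the interpretable contract for a distance model.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import convolve

logger = logging.getLogger(__name__)


class CatalogueError(ValueError):
    """Raised for malformed pressure catalogue inputs."""


#: Ordinal distance classes -> kernel buffer radius in metres.  The open
#: classes "<=1000 m" and ">=25000 m" map to the 1 km and 50 km buffers.
DISTANCE_CLASSES: dict[str, float] = {
    "<=1000": 1_000.0,
    "5000": 5_000.0,
    "10000": 10_000.0,
    "20000": 20_000.0,
    ">=25000": 50_000.0,
}

BUFFER_DISTANCES = (1_000.0, 5_000.0, 10_000.0, 20_000.0, 50_000.0)


def resolve_distance(value) -> float:
    """Map a distance-class label or numeric distance to a buffer radius (m)."""
    if isinstance(value, str):
        key = value.strip().replace(" ", "").replace("m", "")
        if key in DISTANCE_CLASSES:
            return DISTANCE_CLASSES[key]
        try:
            value = float(key)
        except ValueError as exc:
            raise CatalogueError(f"unknown distance class {value!r}") from exc
    dist = float(value)
    if dist <= 0:
        raise CatalogueError(f"propagation distance must be positive, got {dist}")
    if dist <= 1_000.0:
        return 1_000.0
    if dist >= 25_000.0:
        return 50_000.0
    return dist


@dataclass(frozen=True)
class Pressure:
    pressure_id: str
    name: str
    phase: str
    weight: float
    propagation_distance: float  # metres, buffer radius of the kernel
    confidence: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.weight <= 5.0:
            raise CatalogueError(
                f"pressure {self.pressure_id!r}/{self.phase}: weight {self.weight} "
                "outside [0, 5]"
            )
        if self.propagation_distance <= 0:
            raise CatalogueError(
                f"pressure {self.pressure_id!r}: non-positive propagation distance"
            )
        if not 0.2 <= self.confidence <= 1.0:
            raise CatalogueError(
                f"pressure {self.pressure_id!r}: confidence {self.confidence} "
                "outside [0.2, 1]"
            )


@dataclass(frozen=True)
class Kernel:
    """Truncated 2D Gaussian convolution kernel on the analysis grid.

    sigma = radius / 3 with hard truncation at the radius keeps ~99.7% of
    the untruncated Gaussian mass inside the stated buffer; taps are then
    renormalized to sum to exactly 1.
    """

    radius: float
    sigma: float
    window: np.ndarray

    @property
    def is_identity(self) -> bool:
        return self.window.shape == (1, 1)


def build_kernel(distance: float, cell_size: float) -> Kernel:
    """Build the unit-sum truncated Gaussian kernel for a buffer distance.

    The window side is ``2*ceil(distance/cell_size) + 1`` cells; taps are
    proportional to ``exp(-r^2 / (2 sigma^2))`` with ``sigma = distance/3``,
    zero beyond the buffer radius, and renormalized to unit sum.  A distance
    smaller than the cell size degenerates to the 1x1 identity kernel.
    """
    if distance <= 0 or cell_size <= 0:
        raise CatalogueError("distance and cell_size must be positive")
    if distance < cell_size:
        warnings.warn(
            "propagation distance below cell size: using identity kernel",
            stacklevel=2,
        )
        return Kernel(radius=distance, sigma=distance / 3.0, window=np.ones((1, 1)))
    half = int(np.ceil(distance / cell_size))
    sigma = distance / 3.0
    offsets = np.arange(-half, half + 1) * cell_size
    r2 = offsets[:, None] ** 2 + offsets[None, :] ** 2
    window = np.exp(-r2 / (2.0 * sigma**2))
    window[np.sqrt(r2) > distance] = 0.0
    window /= window.sum()
    return Kernel(radius=distance, sigma=sigma, window=window)


def propagate(activity: np.ndarray, kernel: Kernel) -> np.ndarray:
    """Convolve an activity raster with a pressure kernel (zero-padded edges).

    The result is the per-cell pressure intensity; total mass equals the
    activity mass up to whatever the kernel pushes past the open boundary.
    """
    activity = np.asarray(activity, dtype=float)
    if not np.all(np.isfinite(activity)):
        raise ValueError("activity raster contains non-finite values")
    if kernel.is_identity:
        return activity.copy()
    out = convolve(activity, kernel.window, mode="same")
    # convolution of nonnegative inputs; clip FFT round-off below zero
    np.clip(out, 0.0, None, out=out)
    return out


class PressureCatalogue:
    """Phase-keyed pressure catalogue; absent (pressure, phase) pairs weigh 0."""

    def __init__(self, pressures: list[Pressure]):
        self._entries: dict[tuple[str, str], Pressure] = {}
        for p in pressures:
            key = (p.pressure_id, p.phase)
            if key in self._entries:
                raise CatalogueError(
                    f"duplicate catalogue entry for pressure {p.pressure_id!r} "
                    f"in phase {p.phase!r}"
                )
            self._entries[key] = p

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self):
        return iter(self._entries.values())

    @property
    def pressure_ids(self) -> list[str]:
        return sorted({pid for pid, _ in self._entries})

    def for_phase(self, phase: str) -> list[Pressure]:
        return [p for (pid, ph), p in sorted(self._entries.items()) if ph == phase]

    def weight(self, pressure_id: str, phase: str) -> float:
        entry = self._entries.get((pressure_id, phase))
        return entry.weight if entry is not None else 0.0

    def get(self, pressure_id: str, phase: str) -> Pressure | None:
        return self._entries.get((pressure_id, phase))

    def distances(self) -> set[float]:
        return {p.propagation_distance for p in self._entries.values()}


def load_pressure_catalogue(path) -> PressureCatalogue:
    """Load the pressure catalogue from a delimited table.

    Expects columns ``pressure_id, name, phase, weight, distance,
    confidence``; weights outside [0, 5] or confidences outside [0.2, 1]
    are rejected with the offending row number.  Missing (pressure, phase)
    combinations simply stay absent (weight 0 in that phase).
    """
    table = pd.read_csv(path)
    if table.empty:
        warnings.warn(f"pressure catalogue {path} is empty", stacklevel=2)
        return PressureCatalogue([])
    required = {"pressure_id", "name", "phase", "weight", "distance", "confidence"}
    missing = required - set(table.columns)
    if missing:
        raise CatalogueError(f"catalogue missing columns: {sorted(missing)}")
    pressures = []
    for idx, row in table.iterrows():
        try:
            pressures.append(
                Pressure(
                    pressure_id=str(row["pressure_id"]),
                    name=str(row["name"]),
                    phase=str(row["phase"]),
                    weight=float(row["weight"]),
                    propagation_distance=resolve_distance(row["distance"]),
                    confidence=float(row["confidence"]),
                )
            )
        except CatalogueError as exc:
            raise CatalogueError(f"catalogue row {idx}: {exc}") from exc
    return PressureCatalogue(pressures)
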