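"""Free-energy landscapes by Boltzmann inversion and conformational-state
occupancy on the D1 hinge coordinate.

The potential of mean force over one or two descriptors is

    dG = -k_B T ln g,

where g is the normalized (joint) histogram of the sampled descriptor
values, and the minimum over occupied bins is shifted to zero.  Empty bins
are flagged infinite, never capped: a capped value would fabricate barrier
heights.

States partition the D1 axis into closed [0, b1), intermediate [b1, b2) and
open [b2, inf) with half-open intervals (a boundary value belongs to the
upper state).  Defaults b1 = 9.5 Å, b2 = 12.0 Å cut the gaps between the
observed state centers near 8.5, 10.5 and 13.5 Å.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from .geometry import DescriptorSeries

__all__ = [
    "KB_KCAL",
    "PMFGrid",
    "StateDefinition",
    "StateOccupancy",
    "pmf",
    "classify_states",
    "occupancy_table",
    "state_free_energy_difference",
]

#: Boltzmann constant in kcal mol^-1 K^-1.
KB_KCAL = 0.0019872041

STATE_LABELS = ("closed", "intermediate", "open")


@dataclass
class PMFGrid:
    """Binned free-energy landscape in kcal/mol.

    1-D: ``values`` has shape (nx,); 2-D: (nx, ny).  ``occupied`` marks bins
    with at least one sample; unoccupied bins hold +inf.
    """

    axis_names: Tuple[str, ...]
    axis_units: Tuple[str, ...]
    bin_edges: Tuple[np.ndarray, ...]
    values: np.ndarray
    occupied: np.ndarray
    temperature: float

    def __post_init__(self) -> None:
        occ = self.values[self.occupied]
        if occ.size and abs(occ.min()) > 1e-9:
            raise ValueError("occupied PMF minimum must be zero")
        if occ.size and not np.all(np.isfinite(occ)):
            raise ValueError("occupied PMF bins must be finite")

    @property
    def bin_centers(self) -> Tuple[np.ndarray, ...]:
        return tuple((e[:-1] + e[1:]) / 2 for e in self.bin_edges)

    def to_frame(self):
        """Long-format table: bin centers, dG, occupied flag."""
        import pandas as pd

        centers = self.bin_centers
        if len(centers) == 1:
            return pd.DataFrame({
                self.axis_names[0]: centers[0],
                "delta_G_kcal_mol": self.values,
                "occupied": self.occupied,
            })
        xx, yy = np.meshgrid(centers[0], centers[1], indexing="ij")
        return pd.DataFrame({
            self.axis_names[0]: xx.ravel(),
            self.axis_names[1]: yy.ravel(),
            "delta_G_kcal_mol": self.values.ravel(),
            "occupied": self.occupied.ravel(),
        })


def _edges(values: np.ndarray, width: float) -> np.ndarray:
    """Uniform bin edges of the requested width aligned to multiples of it."""
    lo = np.floor(values.min() / width) * width
    hi = np.ceil(values.max() / width) * width
    if hi <= lo + width / 2:
        hi = lo + width
    n = int(round((hi - lo) / width))
    return lo + width * np.arange(n + 1)


def pmf(
    series_x: DescriptorSeries,
    series_y: Optional[DescriptorSeries] = None,
    bin_width: float = 0.1,
    temperature: float = 300.0,
) -> PMFGrid:
    """Boltzmann-inversion free-energy landscape over one or two descriptors.

    ``bin_width`` (default 0.1 Å) applies to every axis.
    """
    if not bin_width > 0:
        raise ValueError("bin width must be positive")
    if not temperature > 0:
        raise ValueError("temperature must be positive")
    x = np.asarray(series_x.values, dtype=float)
    kt = KB_KCAL * temperature
    if series_y is None:
        ex = _edges(x, bin_width)
        hist, _ = np.histogram(x, bins=ex)
        edges = (ex,)
        names = (series_x.name,)
        units = (series_x.units,)
    else:
        y = np.asarray(series_y.values, dtype=float)
        if len(y) != len(x):
            raise ValueError("series lengths differ")
        ex, ey = _edges(x, bin_width), _edges(y, bin_width)
        hist, _, _ = np.histogram2d(x, y, bins=(ex, ey))
        edges = (ex, ey)
        names = (series_x.name, series_y.name)
        units = (series_x.units, series_y.units)
    g = hist / hist.sum()
    occupied = hist > 0
    values = np.full(hist.shape, np.inf)
    with np.errstate(divide="ignore"):
        values[occupied] = -kt * np.log(g[occupied])
    values[occupied] -= values[occupied].min()
    return PMFGrid(axis_names=names, axis_units=units, bin_edges=edges,
                   values=values, occupied=occupied, temperature=temperature)


@dataclass(frozen=True)
class StateDefinition:
    """Closed / intermediate / open partition of the D1 axis (Å)."""

    b1: float = 9.5
    b2: float = 12.0

    def __post_init__(self) -> None:
        if not 0 < self.b1 < self.b2:
            raise ValueError("state boundaries must satisfy 0 < b1 < b2")

    def label(self, d1: float) -> str:
        if d1 < self.b1:
            return "closed"
        if d1 < self.b2:
            return "intermediate"
        return "open"


def classify_states(d1_series: DescriptorSeries,
                    states: StateDefinition = StateDefinition()) -> np.ndarray:
    """Assign each frame its conformational state from the D1 value.

    Boundary values belong to the upper interval (half-open convention).
    """
    x = np.asarray(d1_series.values, dtype=float)
    if np.any(x < 0):
        raise ValueError("negative distances in D1 series")
    labels = np.where(x < states.b1, "closed",
                      np.where(x < states.b2, "intermediate", "open"))
    return labels.astype("U12")


@dataclass
class StateOccupancy:
    """Per-state frame fractions (percent, summing to 100)."""

    fractions: Dict[str, float]
    n_frames: int
    labels: np.ndarray

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if abs(total - 100.0) > 1e-9:
            raise ValueError(f"state fractions sum to {total}, not 100")


def occupancy_table(labels: Sequence[str]) -> StateOccupancy:
    """Exact percent of frames per state; absent states report 0%."""
    labels = np.asarray(labels, dtype="U12")
    if len(labels) == 0:
        raise ValueError("no frames to tabulate")
    fractions = {
        s: 100.0 * np.count_nonzero(labels == s) / len(labels)
        for s in STATE_LABELS
    }
    return StateOccupancy(fractions=fractions, n_frames=len(labels),
                          labels=labels)


def state_free_energy_difference(
    occupancy: StateOccupancy,
    state_a: str,
    state_b: str,
    temperature: float = 300.0,
) -> float:
    """Population free-energy gap dG(a -> b) = -k_B T ln(p_b / p_a), kcal/mol."""
    pa = occupancy.fractions.get(state_a, 0.0)
    pb = occupancy.fractions.get(state_b, 0.0)
    if pa <= 0 or pb <= 0:
        raise ValueError(
            f"undefined ratio: occupancy {state_a}={pa}%, {state_b}={pb}%")
    return float(-KB_KCAL * temperature * np.log(pb / pa))
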