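"""Class-binned climate-analog velocity.

The distance-based ("climate-analog") velocity of a grid cell is the
Euclidean distance from the cell to the nearest cell whose *future* climate
matches the cell's *present* climate, divided by the number of years
separating the two periods.  "Matches" is defined by reclassifying the
continuous climate surface into fixed-width classes — 50 °C·day bins for
GDD, 0.5 °C for T_Jan, 50 mm for WAB — anchored at 0 so class edges are
data- and resolution-independent.

Forward velocity only: each present-day cell searches the future surface.
A present class absent from the entire future surface is a *disappearing
climate*; such cells carry an explicit flag rather than a large distance,
and are excluded from any statistic downstream.

Distances are exact cell-centre Euclidean distances, computed with one
distance transform per present class over the future label raster.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grid import Grid

__all__ = [
    "BinningRule",
    "DEFAULT_RULES",
    "ClassGrid",
    "VelocityGrid",
    "classify",
    "analog_distance",
    "velocity_from_distance",
    "climate_velocity",
    "DEFAULT_YEARS",
]

#: Midpoint separation of the 1981–2010 baseline and 2070–2099 future
#: periods (1995.5 → 2084.5).
DEFAULT_YEARS = 89.0


@dataclass(frozen=True)
class BinningRule:
    """Fixed-width class binning for one climate variable.

    Class ``k`` covers the half-open interval
    ``[anchor + k*width, anchor + (k+1)*width)``.
    """

    variable: str  # one of GDD, TJAN, WAB
    width: float
    anchor: float = 0.0

    def __post_init__(self) -> None:
        if self.variable not in ("GDD", "TJAN", "WAB"):
            raise ValueError("variable must be GDD, TJAN or WAB")
        if self.width <= 0:
            raise ValueError("class width must be > 0")


#: Within-class ranges used for the velocity analysis.
DEFAULT_RULES = {
    "GDD": BinningRule("GDD", 50.0),
    "TJAN": BinningRule("TJAN", 0.5),
    "WAB": BinningRule("WAB", 50.0),
}


@dataclass
class ClassGrid:
    """Integer class-label raster plus the binning rule that produced it."""

    labels: np.ndarray
    rule: BinningRule
    cell_size: float
    origin: tuple[float, float]
    nodata_mask: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def same_frame(self, other: "ClassGrid") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.cell_size, other.cell_size)
            and np.allclose(self.origin, other.origin)
            and self.rule == other.rule
        )


@dataclass
class VelocityGrid:
    """Per-cell velocity (km/yr) with a disappeared-climate flag layer.

    ``velocity.values`` is finite and >= 0 where defined, NaN where the
    climate disappeared or the cell is masked; ``disappeared`` is True only
    on unmasked cells with no analog anywhere in the domain.
    """

    velocity: Grid
    disappeared: np.ndarray
    years: float

    @property
    def defined(self) -> np.ndarray:
        """Unmasked cells with a finite velocity."""
        return ~self.velocity.nodata_mask & ~self.disappeared


def classify(grid: Grid, rule: BinningRule) -> ClassGrid:
    """Reclassify a continuous surface into fixed-width classes.

    ``label = floor((value - anchor) / width)`` — signed, half-open bins;
    the mask is preserved.
    """
    labels = np.floor((grid.values - rule.anchor) / rule.width).astype(np.int64)
    labels[grid.nodata_mask] = np.iinfo(np.int64).min  # never matches
    return ClassGrid(
        labels=labels,
        rule=rule,
        cell_size=grid.cell_size,
        origin=grid.origin,
        nodata_mask=grid.nodata_mask.copy(),
    )


def analog_distance(present: ClassGrid, future: ClassGrid) -> Grid:
    """Distance (m) from each cell to its nearest future climate analog.

    For each unmasked present cell of class ``c``, the Euclidean
    cell-centre distance to the nearest unmasked cell whose future class is
    ``c``; zero when the cell's own future class is ``c``.  ``inf`` marks a
    disappearing climate (no future cell of class ``c`` in the domain).
    One exact Euclidean distance transform per present class.
    """
    if not present.same_frame(future):
        raise ValueError("present and future class grids must share frame and rule")
    out = np.full(present.shape, np.inf)
    valid_p = ~present.nodata_mask
    valid_f = ~future.nodata_mask
    for c in np.unique(present.labels[valid_p]):
        sel = (present.labels == c) & valid_p
        targets = (future.labels == c) & valid_f
        if not targets.any():
            continue  # stays inf: disappearing climate
        d = ndimage.distance_transform_edt(
            ~targets, sampling=present.cell_size
        )
        out[sel] = d[sel]
    grid = Grid(
        values=np.where(valid_p, out, 0.0),
        cell_size=present.cell_size,
        origin=present.origin,
        nodata_mask=present.nodata_mask.copy(),
    )
    # carry the sentinel through the Grid values on unmasked cells
    grid.values[valid_p] = out[valid_p]
    return grid


def velocity_from_distance(dist: Grid, years: float = DEFAULT_YEARS) -> VelocityGrid:
    """Convert analog distances (m) to velocities (km/yr).

    ``velocity = distance / 1000 / years``; infinite distances become the
    ``disappeared`` flag with NaN velocity.
    """
    if years <= 0:
        raise ValueError("years must be > 0")
    valid = ~dist.nodata_mask
    disappeared = np.isinf(dist.values) & valid
    vel = dist.values / 1000.0 / years
    vel = np.where(disappeared | ~valid, np.nan, vel)
    return VelocityGrid(
        velocity=Grid(vel, dist.cell_size, dist.origin, dist.nodata_mask.copy()),
        disappeared=disappeared,
        years=float(years),
    )


def climate_velocity(
    present_var: Grid,
    future_var: Grid,
    rule: BinningRule,
    years: float = DEFAULT_YEARS,
) -> VelocityGrid:
    """classify → analog_distance → velocity, for one variable/scenario."""
    p = classify(present_var, rule)
    f = classify(future_var, rule)
    return velocity_from_distance(analog_distance(p, f), years)
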