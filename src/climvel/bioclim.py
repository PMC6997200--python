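"""Bioclimatic variables from monthly climate normals.

Three variables drive the exposure analysis, chosen for their ecological
relevance at high latitudes:

* **GDD5** — growing degree days, the annual temperature sum above a base
  temperature of 5 °C (°C·days), a proxy for growing-season warmth.
* **T_Jan** — mean January air temperature (°C), a proxy for winter cold.
* **WAB** — climatic water balance (mm), annual precipitation minus
  potential evapotranspiration (PET); negative values indicate drought
  stress.

With monthly normals rather than daily series, GDD5 is estimated at month
level: a month contributes ``(T_m - 5) * days_in_month`` when its mean
``T_m`` exceeds the 5 °C base, otherwise nothing.  PET uses the linear
temperature formula ``PET = 58.93 * mean_m(max(T_m, 0))`` mm/yr, i.e. the
monthly sum ``sum_m 58.93 * max(T_m, 0) / 12``.  A 365-day climatological
calendar (no leap day) is used throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import Grid

__all__ = [
    "DAYS_PER_MONTH",
    "MonthlyNormals",
    "BioclimSet",
    "gdd5",
    "pet",
    "wab",
    "t_jan",
    "compute_bioclim",
]

#: Climatological month lengths (365-day calendar, Jan..Dec).
DAYS_PER_MONTH = (31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31)

#: Skov–Svenning linear PET coefficient (mm per °C per year).
PET_COEFF = 58.93

#: GDD base temperature (°C).
GDD_BASE = 5.0


@dataclass
class MonthlyNormals:
    """Monthly mean temperatures (Jan..Dec) and annual precipitation.

    All 13 grids must share geometry; masks are combined with logical OR
    when deriving variables.
    """

    temps: list[Grid]
    precip_annual: Grid
    days_per_month: tuple[int, ...] = DAYS_PER_MONTH

    def __post_init__(self) -> None:
        if len(self.temps) != 12:
            raise ValueError("exactly 12 monthly temperature grids required")
        if sum(self.days_per_month) != 365:
            raise ValueError("days_per_month must sum to 365")
        g0 = self.temps[0]
        for g in self.temps[1:]:
            if not g0.same_geometry(g):
                raise ValueError("monthly grids must share geometry")
        if not g0.same_geometry(self.precip_annual):
            raise ValueError("precipitation grid must share geometry")

    @property
    def combined_mask(self) -> np.ndarray:
        mask = self.precip_annual.nodata_mask.copy()
        for g in self.temps:
            mask |= g.nodata_mask
        return mask

    def temp_stack(self) -> np.ndarray:
        """(12, rows, cols) array of monthly temperatures."""
        return np.stack([g.values for g in self.temps])


@dataclass
class BioclimSet:
    """The (GDD5, T_Jan, WAB) triple for one period/scenario."""

    gdd: Grid
    t_jan: Grid
    wab: Grid
    period_label: str = ""
    scenario_label: str = ""

    def as_dict(self) -> dict[str, Grid]:
        return {"GDD": self.gdd, "TJAN": self.t_jan, "WAB": self.wab}

    def equals(self, other: "BioclimSet") -> bool:
        for a, b in ((self.gdd, other.gdd), (self.t_jan, other.t_jan),
                     (self.wab, other.wab)):
            if not a.same_geometry(b):
                return False
            if not np.array_equal(a.nodata_mask, b.nodata_mask):
                return False
            ok = ~a.nodata_mask
            if not np.array_equal(a.values[ok], b.values[ok]):
                return False
        return True


def gdd5(normals: MonthlyNormals, base_T: float = GDD_BASE) -> Grid:
    """Growing degree days above ``base_T`` from monthly normals.

    Per cell: ``sum over months m of (T_m - base_T) * days[m]`` restricted
    to months with ``T_m > base_T``; zero when no month qualifies.
    Monotone non-decreasing in every monthly temperature.
    """
    stack = normals.temp_stack()
    days = np.asarray(normals.days_per_month, dtype=float)[:, None, None]
    contrib = np.where(stack > base_T, (stack - base_T) * days, 0.0)
    values = contrib.sum(axis=0)
    mask = normals.combined_mask
    return normals.temps[0].copy_with(np.where(mask, 0.0, values), mask)


def pet(normals: MonthlyNormals) -> Grid:
    """Potential evapotranspiration (mm/yr), linear in temperature.

    ``PET = sum over months of 58.93 * max(T_m, 0) / 12`` — months at or
    below freezing contribute nothing.
    """
    stack = normals.temp_stack()
    values = PET_COEFF * np.clip(stack, 0.0, None).sum(axis=0) / 12.0
    mask = normals.combined_mask
    return normals.temps[0].copy_with(np.where(mask, 0.0, values), mask)


def wab(normals: MonthlyNormals) -> Grid:
    """Climatic water balance: annual precipitation minus PET (mm/yr)."""
    p = pet(normals)
    mask = normals.combined_mask
    values = normals.precip_annual.values - p.values
    return normals.precip_annual.copy_with(np.where(mask, 0.0, values), mask)


def t_jan(normals: MonthlyNormals) -> Grid:
    """Mean January air temperature — the January grid, unchanged."""
    g = normals.temps[0]
    return Grid(g.values.copy(), g.cell_size, g.origin, g.nodata_mask.copy())


def compute_bioclim(
    normals: MonthlyNormals,
    period_label: str = "",
    scenario_label: str = "",
) -> BioclimSet:
    """Compute the full (GDD5, T_Jan, WAB) set from monthly normals.

    The set invariant is a shared mask, so T_Jan carries the combined mask
    of all 13 input grids here (the bare :func:`t_jan` projection keeps
    January's own mask).
    """
    tj = t_jan(normals)
    tj.nodata_mask |= normals.combined_mask
    return BioclimSet(
        gdd=gdd5(normals),
        t_jan=tj,
        wab=wab(normals),
        period_label=period_label,
        scenario_label=scenario_label,
    )
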