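"""Present-day vs future within-PA climate-range overlap and gaps.

For each protected area and climate variable, the within-PA range is the
min–max interval of the variable over the PA's grid cells.  Comparing the
present interval with a scenario's future interval classifies the PA as
*overlap* (intervals intersect; touching endpoints count as overlap, gap
0), *future_above* (the whole future range sits above the present one —
the warming direction for GDD and T_Jan) or *future_below* (drying
direction for WAB), with the gap size between the disjoint intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import Grid
from .exposure import zonal_min_max

__all__ = [
    "RangeOverlapResult",
    "within_pa_range",
    "range_overlap",
    "pa_range_overlap",
    "overlap_summary",
]


@dataclass
class RangeOverlapResult:
    """Overlap/gap verdict for one PA × variable × scenario × track."""

    pa_id: int
    variable: str
    scenario: str
    resolution_track: str  # "fine" or "coarse"
    present_range: tuple[float, float]
    future_range: tuple[float, float]
    overlaps: bool
    gap: float
    direction: str  # "overlap", "future_above", "future_below"


def within_pa_range(var_grid: Grid, polygon) -> tuple[float, float]:
    """Min–max of a climate surface over a PA's unmasked cells."""
    return zonal_min_max(var_grid, polygon)


def range_overlap(
    present: tuple[float, float],
    future: tuple[float, float],
) -> tuple[bool, float, str]:
    """Interval overlap verdict: (overlaps, gap, direction).

    Overlap iff ``present_max >= future_min and future_max >= present_min``
    (touching counts, gap 0); otherwise the gap is the distance between the
    facing interval endpoints.
    """
    p_min, p_max = float(present[0]), float(present[1])
    f_min, f_max = float(future[0]), float(future[1])
    if p_min > p_max or f_min > f_max:
        raise ValueError("malformed interval (min > max)")
    if p_max >= f_min and f_max >= p_min:
        return True, 0.0, "overlap"
    if f_min > p_max:
        return False, f_min - p_max, "future_above"
    return False, p_min - f_max, "future_below"


def pa_range_overlap(
    present_grid: Grid,
    future_grid: Grid,
    polygons: pd.DataFrame,
    variable: str,
    scenario: str,
    resolution_track: str,
) -> pd.DataFrame:
    """Overlap/gap records for every PA on one variable/scenario/track."""
    rows = []
    for pa_id, poly in zip(polygons["pa_id"], polygons["geometry"]):
        pr = within_pa_range(present_grid, poly)
        fr = within_pa_range(future_grid, poly)
        ov, gap, direction = range_overlap(pr, fr)
        rows.append({
            "pa_id": int(pa_id),
            "variable": variable,
            "scenario": scenario,
            "resolution_track": resolution_track,
            "present_min": pr[0], "present_max": pr[1],
            "future_min": fr[0], "future_max": fr[1],
            "overlaps": ov,
            "gap": gap,
            "direction": direction,
        })
    return pd.DataFrame(rows)


def overlap_summary(results: pd.DataFrame) -> pd.DataFrame:
    """Counts of overlapping PAs and mean gap among non-overlapping ones.

    Grouped by variable × scenario × resolution track; ``mean_gap`` is NaN
    when every PA overlaps.
    """
    if len(results) == 0:
        raise ValueError("no overlap results to summarise")

    def _agg(g: pd.DataFrame) -> pd.Series:
        non = g.loc[~g["overlaps"], "gap"]
        return pd.Series({
            "n_pas": len(g),
            "n_overlapping": int(g["overlaps"].sum()),
            "mean_gap": float(non.mean()) if len(non) else np.nan,
        })

    out = (
        results.groupby(["variable", "scenario", "resolution_track"])
        .apply(_agg, include_groups=False)
        .reset_index()
    )
    out["n_pas"] = out["n_pas"].astype(int)
    out["n_overlapping"] = out["n_overlapping"].astype(int)
    return out
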