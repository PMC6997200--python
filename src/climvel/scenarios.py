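"""Future climate scenarios: delta application and bioclim recomputation.

Coarse GCM change fields ("deltas", future minus baseline) are bilinearly
resampled to the working resolution and *added* to the baseline monthly
normals; the bioclimatic variables are then recomputed from the adjusted
monthlies — never delta-adjusted directly — so non-linear variables (GDD's
threshold, PET's freezing clamp) respond correctly.
"""

from __future__ import annotations

from dataclasses import dataclass

from .grid import Grid, bilinear_resample
from .bioclim import MonthlyNormals, BioclimSet, compute_bioclim

__all__ = ["ScenarioClimate", "apply_deltas", "build_scenario"]


@dataclass
class ScenarioClimate:
    """Delta-adjusted normals and their recomputed bioclim for one scenario."""

    scenario_label: str
    normals: MonthlyNormals
    bioclim: BioclimSet


def _resample_to(delta: Grid, template: Grid) -> Grid:
    shape, cs, origin = template.geometry
    return bilinear_resample(delta, cs, shape, origin)


def apply_deltas(
    baseline: MonthlyNormals,
    t_deltas: list[Grid],
    p_delta: Grid,
) -> MonthlyNormals:
    """Add resampled monthly temperature and precipitation deltas.

    Each of the 12 monthly grids receives its bilinearly resampled delta;
    annual precipitation likewise (additive, in mm).  Baseline masks are
    preserved.
    """
    if len(t_deltas) != 12:
        raise ValueError("12 monthly temperature deltas required")
    template = baseline.temps[0]
    temps = []
    for g, d in zip(baseline.temps, t_deltas):
        dd = _resample_to(d, template)
        if dd.nodata_mask[~g.nodata_mask].any():
            raise ValueError("delta field does not cover the baseline extent")
        temps.append(g.copy_with(g.values + dd.values))
    pd_ = _resample_to(p_delta, template)
    if pd_.nodata_mask[~baseline.precip_annual.nodata_mask].any():
        raise ValueError("precipitation delta does not cover the baseline extent")
    precip = baseline.precip_annual.copy_with(
        baseline.precip_annual.values + pd_.values
    )
    return MonthlyNormals(temps=temps, precip_annual=precip,
                          days_per_month=baseline.days_per_month)


def build_scenario(
    baseline: MonthlyNormals,
    t_deltas: list[Grid],
    p_delta: Grid,
    label: str,
) -> ScenarioClimate:
    """Delta-adjust the baseline and recompute the bioclim set."""
    normals = apply_deltas(baseline, t_deltas, p_delta)
    bio = compute_bioclim(normals, period_label="future", scenario_label=label)
    return ScenarioClimate(scenario_label=label, normals=normals, bioclim=bio)
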