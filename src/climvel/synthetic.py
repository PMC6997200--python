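"""Synthetic topoclimatic landscapes for end-to-end testing.

Real inputs to this kind of analysis — a 50-m national topoclimate model, a
GCM delta ensemble, a protected-area (PA) polygon layer — are large and
external.  This module generates stand-ins that carry the *statistical
structure* those data possess, so every downstream stage (aggregation,
bioclim, velocity, zonal exposure, range overlap) can be exercised and
tested without downloads:

* a DEM as a correlated random surface whose height range per 10-km block
  matches a target relief class (1 flatlands < 50 m, 2 undulating 50–200 m,
  3 rugged > 200 m);
* monthly temperature normals built additively from elevation lapse,
  a meridional (north–south) gradient, a radiation (southness) index,
  winter-weighted cold-air pooling in depressions, and noise; annual
  precipitation with an orographic term;
* smooth coarse scenario delta fields with a prescribed mean warming and
  gradient, ordered across RCP scenarios;
* disjoint random PA polygons with log-uniform areas.

All generators are fully deterministic under fixed seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
import shapely
from shapely import affinity
from shapely.geometry import Polygon

from .grid import Grid, aggregate_mean
from .bioclim import MonthlyNormals

__all__ = [
    "ReliefSpec",
    "ClimateGenParams",
    "DeltaSpec",
    "RELIEF_AMPLITUDES",
    "make_dem",
    "make_monthly_climate",
    "make_delta_fields",
    "make_pa_polygons",
    "relief_region_map",
    "default_delta_specs",
]

BLOCK_SIZE_M = 10_000.0  # relief blocks are 10 km x 10 km

#: Default target height range (m) per relief class.
RELIEF_AMPLITUDES = {1: 35.0, 2: 120.0, 3: 350.0}

#: Cold-air-pooling seasonal weight, Jan..Dec: 1 in Dec-Feb, 0 in Jun-Aug,
#: linear in between.
WINTER_WEIGHT = (1.0, 1.0, 0.75, 0.5, 0.25, 0.0, 0.0, 0.0, 0.25, 0.5, 0.75, 1.0)


@dataclass
class ReliefSpec:
    """Terrain class and its height-range target per 10-km block."""

    region_class: int
    relief_amplitude: float | None = None
    correlation_length: float = 2_000.0

    def __post_init__(self) -> None:
        if self.region_class not in (1, 2, 3):
            raise ValueError("region_class must be 1, 2 or 3")
        if self.relief_amplitude is None:
            self.relief_amplitude = RELIEF_AMPLITUDES[self.region_class]
        amp = self.relief_amplitude
        if self.region_class == 1 and not amp < 50:
            raise ValueError("class 1 requires relief_amplitude < 50 m")
        if self.region_class == 2 and not (50 <= amp <= 200):
            raise ValueError("class 2 requires relief_amplitude in [50, 200] m")
        if self.region_class == 3 and not amp > 200:
            raise ValueError("class 3 requires relief_amplitude > 200 m")


@dataclass
class ClimateGenParams:
    """Additive generative terms for monthly topoclimate surfaces.

    Defaults emulate a southern-boreal coastal climate: a 365-day normal
    year spanning roughly -5 °C (January) to +17 °C (July) at sea level,
    standard environmental lapse, a poleward cooling gradient, a radiation
    term worth a few tenths of a degree on slopes, and winter cold-air
    pooling of -0.05 °C per metre of depression depth.

    The meridional gradient is compressed relative to its real per-km value:
    a synthetic domain of a few tens of km stands in for a ~1000-km study
    region, so the default (-0.05 °C/km, about -1 °C across a 20-km domain)
    preserves the domain-scale north-south temperature spread that the
    analog search operates against rather than the literal per-km slope.
    """

    sea_level_monthly_T: tuple[float, ...] = (
        -5.0, -5.5, -2.0, 3.0, 9.0, 14.0, 17.0, 15.5, 10.5, 5.5, 0.5, -3.0
    )
    lapse_rate: float = -0.0065          # °C per metre
    meridional_gradient: float = -0.05   # °C per km of northing
    radiation_coeff: float = 1.5         # °C per unit southness index
    cold_pool_coeff: float = -0.05       # °C per metre of depression depth
    noise_sd: float = 0.3                # °C
    precip_base: float = 550.0           # mm
    orographic_coeff: float = 0.5        # mm per metre of elevation
    precip_noise_sd: float = 30.0        # mm
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.sea_level_monthly_T) != 12:
            raise ValueError("12 monthly sea-level temperatures required")
        if self.noise_sd < 0 or self.precip_noise_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if self.lapse_rate >= 0:
            raise ValueError("lapse_rate must be negative")


@dataclass
class DeltaSpec:
    """One scenario's coarse change field: mean warming, gradient, noise."""

    scenario: str
    mean_warming: float
    warming_gradient: float = 0.0   # °C per km of northing
    precip_change: float = 0.0      # mm
    delta_cell_size: float = 25_000.0
    perturbation_sd: float = 0.0    # °C, smooth spatial perturbation
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in ("RCP2.6", "RCP4.5", "RCP8.5"):
            raise ValueError("scenario must be one of RCP2.6/RCP4.5/RCP8.5")


def default_delta_specs(seed: int = 0) -> list[DeltaSpec]:
    """Scenario ensemble with end-of-century warming ordered 2.6 < 4.5 < 8.5.

    Magnitudes follow typical northern-Europe end-of-century projections:
    +1.5 / +3.0 / +5.0 °C and +20 / +40 / +60 mm annual precipitation.
    """
    return [
        DeltaSpec("RCP2.6", 1.5, precip_change=20.0, seed=seed),
        DeltaSpec("RCP4.5", 3.0, precip_change=40.0, seed=seed + 1),
        DeltaSpec("RCP8.5", 5.0, precip_change=60.0, seed=seed + 2),
    ]


# ---------------------------------------------------------------------------
# DEM
# ---------------------------------------------------------------------------

def _correlated_field(shape, sigma_cells: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance smooth random field (Gaussian-filtered white noise)."""
    noise = rng.standard_normal(shape)
    f = ndimage.gaussian_filter(noise, sigma=sigma_cells, mode="reflect")
    return (f - f.mean()) / f.std()


def make_dem(
    shape: tuple[int, int],
    cell_size: float,
    relief: ReliefSpec,
    seed: int,
    base_elevation: float = 100.0,
) -> Grid:
    """Generate a smooth random DEM with controlled block-wise relief.

    A Gaussian-filtered noise surface is normalised by its *local* height
    range (moving max - min over a 10-km window, smoothed) so that the
    range within any 10-km block matches ``relief.relief_amplitude`` within
    about +-20%.  Deterministic for a fixed seed.
    """
    rows, cols = shape
    if rows < 1 or cols < 1:
        raise ValueError("shape must be positive")
    if cell_size >= BLOCK_SIZE_M:
        raise ValueError("cell_size must be below 10 km (relief blocks undefined)")
    rng = np.random.default_rng(seed)
    sigma = max(relief.correlation_length / cell_size, 1.0)
    f = _correlated_field(shape, sigma, rng)

    # Iteratively rescale so each complete 10-km block's height range
    # converges to the target amplitude; the per-block scale field is
    # upsampled and smoothed so no seams appear at block borders.
    n = min(max(int(round(BLOCK_SIZE_M / cell_size)), 2), rows, cols)
    amp = relief.relief_amplitude
    for _ in range(4):
        br, bc = max(rows // n, 1), max(cols // n, 1)
        v = f[: br * n, : bc * n].reshape(br, n, bc, n)
        block_range = v.max(axis=(1, 3)) - v.min(axis=(1, 3))
        s = np.kron(block_range / amp, np.ones((n, n)))
        s = np.pad(s, ((0, max(rows - s.shape[0], 0)),
                       (0, max(cols - s.shape[1], 0))), mode="edge")
        s = ndimage.gaussian_filter(s[:rows, :cols], sigma=n / 3,
                                    mode="reflect")
        f = f / np.maximum(s, 1e-9)
    dem = f - f.min() + base_elevation
    return Grid(values=dem, cell_size=float(cell_size))


def block_ranges(dem: Grid, block_size_m: float = BLOCK_SIZE_M) -> np.ndarray:
    """Height range (max - min) of each complete 10-km block of the DEM."""
    n = int(round(block_size_m / dem.cell_size))
    rows, cols = dem.shape
    br, bc = rows // n, cols // n
    if br == 0 or bc == 0:
        return np.array([[dem.values.max() - dem.values.min()]])
    v = dem.values[: br * n, : bc * n].reshape(br, n, bc, n)
    return v.max(axis=(1, 3)) - v.min(axis=(1, 3))


def relief_region_map(dem: Grid, block_size_m: float = BLOCK_SIZE_M) -> Grid:
    """Classify 10-km blocks into relief regions 1/2/3 by height range.

    Returns a coarse Grid of integer classes (cell size = block size) whose
    frame is aligned with the DEM origin; partial edge blocks are classified
    from the cells present.
    """
    n = max(int(round(block_size_m / dem.cell_size)), 1)
    rows, cols = dem.shape
    br, bc = -(-rows // n), -(-cols // n)
    classes = np.empty((br, bc))
    for i in range(br):
        for j in range(bc):
            blk = dem.values[i * n:(i + 1) * n, j * n:(j + 1) * n]
            rng_ = blk.max() - blk.min()
            classes[i, j] = 1 if rng_ < 50 else (2 if rng_ <= 200 else 3)
    return Grid(values=classes, cell_size=dem.cell_size * n, origin=dem.origin)


# ---------------------------------------------------------------------------
# Monthly climate
# ---------------------------------------------------------------------------

def _southness_index(dem: Grid) -> np.ndarray:
    """Radiation loading index: positive on south-facing slopes.

    Computed from the terrain gradient as the southward component of the
    downslope direction scaled by slope steepness — approximately
    ``sin(slope) * cos(aspect - south)`` for moderate slopes.
    """
    if dem.shape[0] < 2 or dem.shape[1] < 2:
        return np.zeros(dem.shape)
    # row index increases southwards
    dz_drow, dz_dcol = np.gradient(dem.values, dem.cell_size)
    gy_north = -dz_drow  # derivative towards north
    slope_mag = np.hypot(gy_north, dz_dcol)
    denom = np.sqrt(1.0 + slope_mag**2)
    return gy_north / denom


def _relative_elevation(dem: Grid, window_m: float = 1_000.0) -> np.ndarray:
    """Elevation minus the focal-mean elevation over ``window_m``."""
    win = max(int(round(window_m / dem.cell_size)), 3)
    focal = ndimage.uniform_filter(dem.values, size=win, mode="reflect")
    return dem.values - focal


def make_monthly_climate(dem: Grid, params: ClimateGenParams) -> MonthlyNormals:
    """Generate 12 monthly temperature grids and annual precipitation.

    Monthly temperature is the additive sum of a sea-level month normal,
    elevation lapse, a meridional gradient on the northing coordinate, a
    radiation (southness) term, a winter-weighted cold-air-pooling term on
    depression depth, and white noise.  Precipitation is a base plus an
    orographic elevation term plus noise.  Deterministic per seed.
    """
    rng = np.random.default_rng(params.seed)
    _, y = dem.cell_centers()
    y_km = y / 1000.0
    rad = _southness_index(dem)
    rel = _relative_elevation(dem)
    depth = np.maximum(-rel, 0.0)  # metres below the local mean surface

    temps = []
    for m in range(12):
        t = (
            params.sea_level_monthly_T[m]
            + params.lapse_rate * dem.values
            + params.meridional_gradient * y_km
            + params.radiation_coeff * rad
            + params.cold_pool_coeff * depth * WINTER_WEIGHT[m]
        )
        if params.noise_sd > 0:
            t = t + rng.normal(0.0, params.noise_sd, size=dem.shape)
        temps.append(dem.copy_with(t))

    precip = params.precip_base + params.orographic_coeff * dem.values
    if params.precip_noise_sd > 0:
        precip = precip + rng.normal(0.0, params.precip_noise_sd, size=dem.shape)
    return MonthlyNormals(temps=temps, precip_annual=dem.copy_with(precip))


# ---------------------------------------------------------------------------
# Scenario delta fields
# ---------------------------------------------------------------------------

def make_delta_fields(
    spec: DeltaSpec,
    target_geometry: tuple[tuple[int, int], float, tuple[float, float]],
) -> tuple[list[Grid], Grid]:
    """Generate coarse monthly temperature deltas and a precipitation delta.

    The coarse frame covers the target extent with at least a 2x2 cell
    support (padded one cell beyond each edge).  Each field is
    ``mean_warming + warming_gradient * (northing - centre)`` plus an
    optional smooth perturbation; the 12 monthly fields share the same
    spatial pattern.  Deterministic per seed.
    """
    (t_rows, t_cols), t_cs, (ox, oy) = target_geometry
    if spec.delta_cell_size < t_cs:
        raise ValueError("delta_cell_size must be >= target cell size")
    cs = float(spec.delta_cell_size)
    width = t_cols * t_cs
    height = t_rows * t_cs
    cols = max(int(np.ceil(width / cs)) + 2, 2)
    rows = max(int(np.ceil(height / cs)) + 2, 2)
    origin = (ox - cs, oy + cs)

    y = origin[1] - (np.arange(rows) + 0.5) * cs
    y_km = np.broadcast_to(y[:, None], (rows, cols)).astype(float)
    centre_km = (oy - height / 2.0) / 1000.0
    base = spec.mean_warming + spec.warming_gradient * (y_km / 1000.0 - centre_km)

    rng = np.random.default_rng(spec.seed)
    t_deltas = []
    for _ in range(12):
        f = base.copy()
        if spec.perturbation_sd > 0:
            f = f + ndimage.gaussian_filter(
                rng.normal(0.0, spec.perturbation_sd, size=(rows, cols)),
                sigma=1.0, mode="reflect",
            )
        t_deltas.append(Grid(values=f, cell_size=cs, origin=origin))
    p = np.full((rows, cols), spec.precip_change, dtype=float)
    if spec.perturbation_sd > 0:
        p = p + ndimage.gaussian_filter(
            rng.normal(0.0, spec.perturbation_sd, size=(rows, cols)),
            sigma=1.0, mode="reflect",
        )
    p_delta = Grid(values=p, cell_size=cs, origin=origin)
    return t_deltas, p_delta


# ---------------------------------------------------------------------------
# Protected-area polygons
# ---------------------------------------------------------------------------

def make_pa_polygons(
    domain_geometry: tuple[tuple[int, int], float, tuple[float, float]],
    n: int,
    area_range_ha: tuple[float, float] = (2.0, 100.0),
    seed: int = 0,
    n_vertices: int = 24,
    radius_jitter: float = 0.25,
    max_tries_per_polygon: int = 200,
) -> "pd.DataFrame":
    """Place ``n`` disjoint random PA polygons inside the domain.

    Each polygon is a star-convex blob: a ring of vertices at jittered radii
    around a random centre, rescaled to a log-uniformly drawn target area
    (hectares).  Polygons are pairwise disjoint and fully inside the domain.
    Returns a DataFrame with columns ``pa_id`` (1-based int) and
    ``geometry`` (shapely Polygon).  Raises ``RuntimeError`` when placement
    fails after bounded retries.
    """
    import pandas as pd

    if n < 1:
        raise ValueError("n must be >= 1")
    lo, hi = float(area_range_ha[0]), float(area_range_ha[1])
    if lo < 2.0:
        raise ValueError("minimum PA area is 2 ha")
    if hi < lo:
        raise ValueError("invalid area range")
    (rows, cols), cs, (ox, oy) = domain_geometry
    xmin, xmax = ox, ox + cols * cs
    ymin, ymax = oy - rows * cs, oy
    rng = np.random.default_rng(seed)

    placed: list[Polygon] = []
    angles = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    for _ in range(n):
        area_m2 = np.exp(rng.uniform(np.log(lo), np.log(hi))) * 10_000.0
        ok = None
        for _try in range(max_tries_per_polygon):
            r0 = np.sqrt(area_m2 / np.pi)
            if xmin + 2 * r0 >= xmax - 2 * r0 or ymin + 2 * r0 >= ymax - 2 * r0:
                continue  # polygon cannot fit this domain; burn a retry
            radii = r0 * (1.0 + rng.uniform(-radius_jitter, radius_jitter,
                                            size=n_vertices))
            cx = rng.uniform(xmin + 2 * r0, xmax - 2 * r0)
            cy = rng.uniform(ymin + 2 * r0, ymax - 2 * r0)
            poly = Polygon(np.column_stack([
                cx + radii * np.cos(angles), cy + radii * np.sin(angles)
            ]))
            # rescale about the centroid so the area matches the draw exactly
            s = np.sqrt(area_m2 / poly.area)
            poly = affinity.scale(poly, xfact=s, yfact=s, origin="centroid")
            b = poly.bounds
            if b[0] < xmin or b[1] < ymin or b[2] > xmax or b[3] > ymax:
                continue
            if any(poly.intersects(q) for q in placed):
                continue
            ok = poly
            break
        if ok is None:
            raise RuntimeError(
                f"could not place {n} disjoint polygons (stuck after "
                f"{max_tries_per_polygon} tries at polygon {len(placed) + 1})"
            )
        placed.append(ok)
    return pd.DataFrame({
        "pa_id": np.arange(1, n + 1, dtype=int),
        "geometry": placed,
    })


def write_pa_polygons(df, path) -> None:
    """Write PA polygons as a WKT CSV (columns pa_id, wkt)."""
    import pandas as pd

    out = pd.DataFrame({
        "pa_id": df["pa_id"].astype(int),
        "wkt": [g.wkt for g in df["geometry"]],
    })
    out.to_csv(path, index=False)


def read_pa_polygons(path):
    """Read PA polygons from a WKT CSV written by :func:`write_pa_polygons`."""
    import pandas as pd

    raw = pd.read_csv(path)
    return pd.DataFrame({
        "pa_id": raw["pa_id"].astype(int),
        "geometry": [shapely.from_wkt(w) for w in raw["wkt"]],
    })
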