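# Methods

## Model and procedure

The package measures distance-based (climate-analog) velocity on gridded
climate surfaces. For one climate variable and one scenario:

1. the continuous present and future surfaces are reclassified into
   fixed-width classes, `label = floor((value − anchor) / width)`;
2. each unmasked present-day cell of class *c* searches the *future* label
   raster for the nearest unmasked cell of class *c* (forward search; the
   cell's own location qualifies at distance 0);
3. the Euclidean cell-centre distance is divided by the period separation in
   years and reported in km/yr. A present class absent from the whole
   future surface is a disappearing climate: the cell is flagged and
   excluded from every downstream statistic rather than assigned an
   arbitrary large distance.

Distances are computed with one exact Euclidean distance transform per
present class over the future label raster; a brute-force all-pairs search
is kept in the test suite as the correctness oracle and the two agree
exactly on random instances.

Assumptions worth stating: velocity is a per-variable scalar speed (no
bearing, no multivariate climate space); the search is isotropic and
unconstrained by barriers other than the nodata mask; analogs are defined by
class membership, so the within-class range sets the precision of "similar
climate".

## Bioclimatic variables

* **GDD5** (°C·day): monthly estimation, `Σ_m (T_m − 5)·days_m` over months
  with `T_m > 5 °C`, on a 365-day climatological calendar. The month-block
  rule (no sub-monthly interpolation) is the package's reading of the
  standard monthly approximation.
* **PET** (mm/yr): `58.93 · Σ_m max(T_m, 0) / 12` — the linear temperature
  formula with per-month clamping at 0 °C before averaging.
* **WAB** (mm/yr): annual precipitation minus PET; may be negative.
* **T_Jan** (°C): the January grid.

Future variables are always recomputed from delta-adjusted monthly normals,
never shifted directly, so the GDD threshold and PET clamp respond
non-linearly where months cross 5 °C or 0 °C.

## Class binning

Default within-class ranges: GDD 50 °C·day, T_Jan 0.5 °C, WAB 50 mm. The
bin anchor is fixed at 0 in variable units, which makes class edges
data-independent and identical across resolutions and scenarios — a
prerequisite for comparing the two resolution tracks. Bins are half-open
`[k·w, (k+1)·w)`. Ties between equidistant analogs are irrelevant because
only the distance is retained.

The period separation defaults to 89 years — the midpoint separation of a
1981–2010 baseline and a 2070–2099 future (1995.5 → 2084.5) — and is
configurable.

## Raster conventions and numerics

* Upper-left origin, row-major, cell-centre registration; all distances are
  between cell centres. GeoTIFF I/O requires a projected CRS in metres and
  refuses degree-based rasters.
* Areal-mean aggregation: a coarse cell is the mean of the unmasked fine
  cells it covers and is masked only when all of them are masked; partial
  blocks at the right/bottom edges average over the cells present, so
  domains need not be multiples of the aggregation factor.
* Bilinear resampling interpolates between coarse cell centres, excludes
  masked samples by renormalising the four corner weights, masks the output
  only where all four corners are masked, and clamps (constant-extrapolates)
  beyond the outermost centres so a coarse delta field still serves fine
  border cells. Bilinear interpolation is exact on constants and planes,
  which the tests exploit.
* Zonal membership is centre-in-polygon, with a fallback to all cells whose
  footprint intersects the polygon for PAs too small to contain a cell
  centre (a 2-ha PA against a 1-km track). Within-PA ranges are min–max
  over the member cells, not quantiles.
* Interval overlap: touching intervals (present max = future min) count as
  overlapping with gap 0; the gap of disjoint intervals is the distance
  between the facing endpoints, with the direction recorded as
  `future_above` or `future_below`.

## PA statistics

Per-PA mean velocities use unmasked, non-disappeared cells only; the
disappeared fraction is reported separately, and a PA whose climate has
entirely disappeared gets a NaN mean, is excluded from hotspot rankings, and
keeps its flag. Hotspots are the `floor(0.05·N)` PAs with the highest mean
velocity, ties broken by ascending PA id for determinism; with N = 5,068
records that is exactly 253 sites. Hotspot overlap percentages are
`|A∩B|/|A|` relative to the first-named variable.

The fine-vs-coarse comparison uses the symmetric relative difference
`RD = (coarse − fine) / ((coarse + fine)/2)`, bounded in (−2, 2) and
positive where the coarse velocity is larger; the asymmetric
`(coarse − fine)/fine` was rejected as unstable near `fine → 0`. RD is
undefined (and the record excluded, with a warning) only when both
velocities are zero.

The GLM is Gaussian with identity link: RD on relief region (ordinal,
coded 1–3 as a single linear term), natural-log PA area (ha), natural-log
within-PA elevation range (m), and scenario as a categorical factor. Effect
sizes follow the min–max prediction-range rule — the response-scale change
between a predictor's observed minimum and maximum with the other predictors
held at their means — which for the identity link equals
|coefficient| × observed range (asserted analytically in the tests); the
slope's sign is recorded alongside the magnitude. Rank deficiency (a
constant covariate) raises an explicit error.

## Synthetic landscapes: what they emulate, and what not

The generator produces the statistical structure the pipeline needs:

* **DEM**: Gaussian-filtered noise (correlation length 2 km by default)
  iteratively rescaled so the height range of every complete 10-km block
  matches the relief-class target within about ±20% (class 1 < 50 m,
  class 2 50–200 m, class 3 > 200 m; defaults 35 / 120 / 350 m).
* **Monthly temperature** = sea-level month normal + lapse (−0.0065 °C/m)
  + meridional gradient + radiation (southness) term (1.5 °C per unit
  index) + cold-air pooling (−0.05 °C per metre of depression depth,
  weighted 1 in Dec–Feb, 0 in Jun–Aug, linear between — winter decoupling
  is the regime where topoclimate models disagree most with coarse data)
  + Gaussian noise (0.3 °C). **Precipitation** = 550 mm + 0.5 mm/m of
  elevation + noise (30 mm), generated annually because only annual
  precipitation enters WAB.
* The **meridional gradient** default (−0.05 °C/km) is compressed relative
  to a real per-km continental gradient: a domain of tens of km stands in
  for a ~1000-km study region, and what matters to the analog search is the
  domain-scale north–south climate spread, not the literal slope.
* **Delta fields**: coarse (25-km cells by default) smooth surfaces with
  prescribed mean warming and optional gradient/perturbation; default
  ensemble +1.5 / +3.0 / +5.0 °C and +20 / +40 / +60 mm for RCP2.6 / 4.5 /
  8.5, typical of end-of-century northern-Europe projections.
* **PA polygons**: star-convex blobs with log-uniform areas (2–100 ha by
  default), pairwise disjoint (each physically separate site is one PA) and
  fully inside the domain; placement is rejection-sampled with a bounded
  retry budget and an explicit error on failure.

Everything is deterministic under fixed seeds.

What the generator does **not** emulate: real station interpolation and its
error structure, coastlines, lakes and sea-proximity effects, real GCM
ensemble spread, spatially varying relief within one landscape (each
landscape carries a single macro-scale relief class, mirroring a regional
relief division), or realistic PA shapes. Passing tests therefore
demonstrate that the *method* behaves as specified — including the
direction and rough magnitude of the resolution effect — not that any
particular real-world velocity value is reproduced.

A consequence of the small domain is that disappearing climates are more
common than on a national grid: a +3 °C shift exceeds the whole domain's
GDD range on flat landscapes, so coarse-track analogs often vanish where
fine-track analogs survive in topoclimatic pockets. This is the expected
behaviour of the method at this scale and is surfaced through the
disappeared flags rather than suppressed.

## Problem sizes

Default experiment: 400×400 fine cells at 50 m (20 km × 20 km), aggregation
factor 20 (20×20 coarse cells at 1 km), 200 PAs of 2–100 ha, three
scenarios, three variables, both tracks — a few seconds per landscape. The
resolution-effect checks pool five seeded landscapes; the mixed-relief GLM
check pools six (three each of relief classes 2 and 3) using the mildest
scenario, where both tracks retain analogs.

## Known limitations

* Velocity is univariate; no PCA-space or multivariate analog search.
* No gradient-based (local slope) velocity variant.
* The nodata mask is the only movement barrier; water bodies are not
  modelled.
* Hotspot counts at the synthetic scale (hundreds of PAs) are small, so
  cross-variable hotspot overlap percentages are coarse-grained.
* The GLM ignores spatial autocorrelation among PAs.
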