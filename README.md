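# climvel

Fine-grained climate-analog velocity and climate-range exposure analysis for
protected-area (PA) networks.

## The problem

Protected areas are fixed in place while climate moves. A standard way to
quantify that exposure is the **distance-based (climate-analog) velocity**:
for every grid cell, find the nearest cell whose *future* climate falls in
the same class as the cell's *present* climate, and divide the distance by
the number of years separating the two periods,

```
v = min distance(present cell -> future analog) / Δt      [km/yr]
```

A present-day class with no future analog anywhere in the domain is a
*disappearing climate* and is flagged instead of given a distance.

The velocity depends strongly on the grain of the climate data. Terrain
creates topoclimate — radiation loading on south-facing slopes, cold-air
pooling in hollows, elevation lapse — that survives in a 50-m climate
surface but is averaged away at 1-km resolution. Climate analogs that sit a
hillside away at 50 m can appear tens of kilometres away at 1 km, so coarse
data systematically overstate the exposure of reserves in rugged terrain.
This package implements the full comparison pipeline at both resolutions:

1. **Bioclimatic variables** from monthly normals: growing degree days above
   5 °C (`GDD5 = Σ_m (T_m − 5)·days_m` over months with `T_m > 5`), mean
   January temperature `T_Jan`, and the climatic water balance
   `WAB = P − PET` with the linear temperature PET,
   `PET = 58.93 · Σ_m max(T_m, 0) / 12` (mm/yr).
2. **Resolution tracks**: areal-mean aggregation of fine surfaces onto a
   coarse grid (e.g. factor 20, 50 m → 1 km).
3. **Scenario futures**: coarse GCM delta fields bilinearly resampled to each
   working resolution, added to the baseline monthlies, and the bioclim
   variables recomputed per scenario (RCP2.6 / RCP4.5 / RCP8.5).
4. **Analog velocity** with fixed-width classes (GDD 50 °C·day, T_Jan
   0.5 °C, WAB 50 mm), exact Euclidean nearest-analog distances and
   disappearing-climate flags.
5. **PA exposure**: zonal mean velocities per PA polygon (≥ 2 ha), top-5%
   velocity hotspots and their cross-variable overlap, paired t-tests of
   coarse vs fine velocities by relief region, symmetric relative
   differences `RD = (v_coarse − v_fine) / ((v_coarse + v_fine)/2)`, and a
   Gaussian GLM of RD on relief region, log PA area, log within-PA elevation
   range and scenario, with min–max prediction-range effect sizes.
6. **Range overlap**: present vs future within-PA min–max climate ranges,
   overlap/gap/direction per variable, scenario and resolution track.

A synthetic-landscape module generates DEMs with controlled relief classes
(flat / undulating / rugged, by height range per 10-km block), additive
topoclimatic monthly normals, scenario-ordered delta fields and disjoint
random PA polygons, so the whole pipeline runs and is tested end-to-end
without external data.

## Worked example

```python
import climvel as cv

res = cv.run_experiment(cv.ExperimentConfig(seed=1, shape=(300, 300), n_pas=100))
pt = res.pa_table

gdd = pt[(pt.variable == "GDD") & pt.rel_diff.notna()]
print(f"PAs with a defined GDD velocity on both tracks: {len(gdd)}")
share = (gdd.mean_velocity_coarse > gdd.mean_velocity_fine).mean()
print(f"coarse (1-km) velocity exceeds fine (50-m) velocity in {share:.0%} of them")

t = cv.paired_velocity_test(gdd.mean_velocity_fine, gdd.mean_velocity_coarse)
print(f"paired t = {t['t']:.1f}, p = {t['p']:.1e}, "
      f"mean difference = {t['mean_diff']:.3f} km/yr")

summ = cv.overlap_summary(res.overlap_table)
print(summ[summ.variable == "TJAN"].to_string(index=False))
```

Output:

```
PAs with a defined GDD velocity on both tracks: 90
coarse (1-km) velocity exceeds fine (50-m) velocity in 100% of them
paired t = 17.9, p = 3.7e-31, mean difference = 0.025 km/yr
variable scenario resolution_track  n_pas  n_overlapping  mean_gap
    TJAN   RCP2.6           coarse    100              0  1.366903
    TJAN   RCP2.6             fine    100             36  0.327773
    TJAN   RCP4.5           coarse    100              0  2.866903
    TJAN   RCP4.5             fine    100              0  1.634297
    TJAN   RCP8.5           coarse    100              0  4.866903
    TJAN   RCP8.5             fine    100              0  3.634297
```

On this rugged (relief class 3) synthetic landscape the coarse track
overstates every PA's GDD exposure (paired t = 17.9 on 90 PAs with analogs
on both tracks; the remaining PAs have no coarse-track analog at all —
their climate disappears only when topoclimate is smoothed away). For
January temperature, within-PA present and future ranges still overlap in
36/100 PAs at fine resolution under the mildest scenario but in none at
coarse resolution, and where ranges are disjoint the gap is larger on the
coarse track — topoclimate buffers the apparent exposure.

A thin CLI covers the raster plumbing:

```sh
climvel synth-landscape --relief 3 --seed 42 --out land/
climvel bioclim --temps land/t01.tif ... land/t12.tif --precip land/precip.tif --out-prefix now_
climvel velocity --present now_gdd.tif --future future_gdd.tif --var GDD --years 89 --out vel.tif
climvel grid-aggregate --factor 20 land/dem.tif dem_1km.tif
```

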