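"""Zonal statistics, hotspot selection, paired tests, relative differences
and the GLM of relative differences."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from climvel import (
    Grid,
    top_fraction,
    hotspot_overlap,
    paired_velocity_test,
    relative_difference,
    glm_relative_diff,
    zonal_mean,
)
from climvel.velocity import VelocityGrid
from climvel.exposure import cells_in_polygon


def velocity_grid(values, cell=50.0, disappeared=None, mask=None):
    values = np.asarray(values, dtype=float)
    if disappeared is None:
        disappeared = np.zeros(values.shape, bool)
    vals = np.where(disappeared, np.nan, values)
    g = Grid(vals, cell, (0.0, values.shape[0] * cell),
             nodata_mask=mask if mask is not None else np.zeros(values.shape, bool))
    return VelocityGrid(velocity=g, disappeared=disappeared, years=89.0)


def pa_frame(polys):
    return pd.DataFrame({"pa_id": range(1, len(polys) + 1), "geometry": polys})


class TestZonalMean:
    def test_constant_field(self):
        vg = velocity_grid(np.full((10, 10), 0.7))
        pas = pa_frame([box(50, 50, 350, 350), box(400, 100, 480, 180)])
        out = zonal_mean(vg, pas)
        assert np.allclose(out["mean_velocity_kmyr"], 0.7)

    def test_two_cell_average(self):
        vals = np.zeros((1, 2))
        vals[0, 0], vals[0, 1] = 1.0, 3.0
        vg = velocity_grid(vals)
        pas = pa_frame([box(0, 0, 100, 50)])
        out = zonal_mean(vg, pas)
        assert out.loc[0, "mean_velocity_kmyr"] == 2.0
        assert out.loc[0, "n_cells"] == 2

    def test_disappeared_excluded_from_mean(self):
        vals = np.array([[1.0, 3.0], [5.0, 7.0]])
        dis = np.array([[False, True], [False, True]])
        vg = velocity_grid(vals, disappeared=dis)
        pas = pa_frame([box(0, 0, 100, 100)])
        out = zonal_mean(vg, pas)
        assert out.loc[0, "frac_disappeared"] == 0.5
        assert out.loc[0, "mean_velocity_kmyr"] == 3.0  # mean of 1 and 5

    def test_fully_disappeared_pa_flagged(self):
        vg = velocity_grid(np.ones((2, 2)), disappeared=np.ones((2, 2), bool))
        out = zonal_mean(vg, pa_frame([box(0, 0, 100, 100)]))
        assert np.isnan(out.loc[0, "mean_velocity_kmyr"])
        assert out.loc[0, "frac_disappeared"] == 1.0

    def test_tiny_polygon_intersection_fallback(self):
        g = Grid(np.arange(4, dtype=float).reshape(2, 2), 100.0, (0.0, 200.0))
        tiny = box(10, 150, 30, 170)  # inside cell (0, 0), misses its centre
        r, c = cells_in_polygon(g, tiny)
        assert (r.tolist(), c.tolist()) == ([0], [0])

    def test_polygon_outside_grid_rejected(self):
        vg = velocity_grid(np.ones((2, 2)))
        with pytest.raises(ValueError):
            zonal_mean(vg, pa_frame([box(10_000, 10_000, 10_100, 10_100)]))

    def test_elev_range_and_relief(self):
        vg = velocity_grid(np.ones((4, 4)))
        dem = Grid(np.arange(16, dtype=float).reshape(4, 4), 50.0, (0.0, 200.0))
        out = zonal_mean(vg, pa_frame([box(0, 0, 200, 200)]), dem=dem,
                         relief_lookup=lambda x, y: 2)
        assert out.loc[0, "elev_range_m"] == 15.0
        assert out.loc[0, "relief_region"] == 2


class TestTopFraction:
    def test_printed_hotspot_count(self):
        rng = np.random.default_rng(0)
        rec = pd.DataFrame({"pa_id": np.arange(1, 5069),
                            "mean_velocity_kmyr": rng.random(5068)})
        assert len(top_fraction(rec, 0.05)) == 253

    def test_exact_fraction(self):
        rec = pd.DataFrame({"pa_id": np.arange(1, 101),
                            "mean_velocity_kmyr": np.arange(100.0)})
        ids = top_fraction(rec, 0.05)
        assert ids == [100, 99, 98, 97, 96]

    def test_tie_break_by_pa_id(self):
        rec = pd.DataFrame({"pa_id": np.arange(1, 41),
                            "mean_velocity_kmyr": np.ones(40)})
        assert top_fraction(rec, 0.05) == [1, 2]

    def test_floor_rule_over_all_sizes(self):
        rng = np.random.default_rng(1)
        for n in range(1, 201):
            rec = pd.DataFrame({"pa_id": np.arange(1, n + 1),
                                "mean_velocity_kmyr": rng.random(n)})
            assert len(top_fraction(rec, 0.05)) == int(np.floor(0.05 * n))

    def test_nan_records_counted_but_not_ranked(self):
        rec = pd.DataFrame({"pa_id": np.arange(1, 41),
                            "mean_velocity_kmyr": np.arange(40.0)})
        rec.loc[rec["pa_id"] == 40, "mean_velocity_kmyr"] = np.nan
        ids = top_fraction(rec, 0.05)
        assert len(ids) == 2 and 40 not in ids

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            top_fraction(pd.DataFrame(columns=["pa_id", "mean_velocity_kmyr"]))


class TestHotspotOverlap:
    def test_identical_sets(self):
        out = hotspot_overlap({1, 2, 3}, {1, 2, 3})
        assert out["pct_shared"] == 100.0

    def test_disjoint_sets(self):
        out = hotspot_overlap({1, 2}, {3, 4})
        assert out["n_shared"] == 0 and out["pct_shared"] == 0.0

    def test_partial_and_triple(self):
        out = hotspot_overlap(set(range(1, 11)), set(range(6, 16)),
                              set(range(8, 20)))
        assert out["n_shared"] == 5
        assert out["pct_shared"] == 50.0
        assert out["n_shared_triple"] == 3


class TestPairedTest:
    def test_closed_form_t(self):
        r = paired_velocity_test(np.zeros(5), np.array([2.0, -1.0, 3.0, 0.0, 1.0]))
        assert np.isclose(r["t"], np.sqrt(2.0))
        d = np.array([2.0, -1.0, 3.0, 0.0, 1.0])
        assert np.isclose(r["t"], d.mean() / (d.std(ddof=1) / np.sqrt(5)),
                          atol=1e-10)

    def test_equal_pairs(self):
        r = paired_velocity_test(np.ones(4), np.ones(4))
        assert r["t"] == 0.0 and r["prop_coarse_gt_fine"] == 0.0
        assert not r["degenerate"]

    def test_zero_variance_flagged_not_crashing(self):
        r = paired_velocity_test(np.zeros(4), np.ones(4))
        assert r["degenerate"] and np.isinf(r["t"])
        assert r["prop_coarse_gt_fine"] == 1.0

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            paired_velocity_test([1.0], [2.0])


class TestRelativeDifference:
    def test_examples(self):
        assert relative_difference(2.0, 2.0) == 0.0
        assert relative_difference(1.0, 3.0) == 1.0
        assert relative_difference(3.0, 1.0) == -1.0

    def test_bounded_and_sign(self):
        rng = np.random.default_rng(0)
        f = rng.uniform(0, 5, 1000)
        c = rng.uniform(0, 5, 1000)
        rd = relative_difference(f, c)
        assert np.all(np.abs(rd) <= 2.0)
        assert np.all((rd > 0) == (c > f))

    def test_both_zero_warns_nan(self):
        with pytest.warns(UserWarning):
            rd = relative_difference(np.array([0.0, 1.0]), np.array([0.0, 3.0]))
        assert np.isnan(rd[0]) and rd[1] == 1.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            relative_difference(-1.0, 1.0)


def simulate_records(n, beta_elev=0.3, noise=0.2, seed=1):
    rng = np.random.default_rng(seed)
    elev = np.exp(rng.uniform(np.log(5), np.log(500), n))
    return pd.DataFrame({
        "rel_diff": 0.1 + beta_elev * np.log(elev) + rng.normal(0, noise, n),
        "relief_region": rng.integers(1, 4, n),
        "area_ha": np.exp(rng.uniform(np.log(2), np.log(1000), n)),
        "elev_range_m": elev,
        "scenario": rng.choice(["RCP2.6", "RCP4.5", "RCP8.5"], n),
    })


class TestGlm:
    def test_parameter_recovery(self):
        res = glm_relative_diff(simulate_records(500))
        beta = res.params["log_elev_range"]
        se = res.model_result.bse["log_elev_range"]
        assert abs(beta - 0.3) < 3 * se

    def test_effect_size_is_coef_times_range(self):
        df = simulate_records(300)
        res = glm_relative_diff(df)
        rng_cov = np.log(df["elev_range_m"]).max() - np.log(df["elev_range_m"]).min()
        assert np.isclose(res.effect_sizes["log_elev_range"],
                          abs(res.params["log_elev_range"]) * rng_cov)
        assert res.effect_signs["log_elev_range"] == 1

    def test_null_predictor_effect_shrinks(self):
        res = glm_relative_diff(simulate_records(2000, seed=3))
        # log_area has zero true coefficient
        assert res.effect_sizes["log_area"] < 0.05

    def test_rank_deficiency_reported(self):
        df = simulate_records(100)
        df["relief_region"] = 2
        with pytest.raises(ValueError, match="rank"):
            glm_relative_diff(df)

    def test_minimum_sample_size(self):
        with pytest.raises(ValueError):
            glm_relative_diff(simulate_records(10))
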