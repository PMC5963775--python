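"""Fire-regime statistics: burned-area tables, survival/FRI, trends,
patch sizes, gridded epochs."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from firescape import reference
from firescape.objects import ChangeObject
from firescape.regime import (annual_burned_table, epoch_edges, fit_fri,
                              grid_epoch_summary, large_patch_trend,
                              mann_kendall, patch_size_distribution,
                              slope_percent, survival_curve, theil_sen,
                              trend_test, zone_stats)


def fire_object(oid, pixels, year):
    o = ChangeObject(object_id=oid, change_year=year, duration_yr=1,
                     pixels=np.asarray(pixels))
    o.label = "fire"
    o.area_ha = len(pixels) * 0.09
    return o


YEARS = np.arange(1990, 2000)
ZONES = ("A", "B")


def simple_zone_map(n=40):
    zm = np.zeros((n, n), dtype=np.int32)
    zm[:, n // 2:] = 1
    return zm


# ---------------------------------------------------------------------------
# annual burned area

def test_no_fire_objects_give_zero_table():
    zm = simple_zone_map()
    table = annual_burned_table([], zm, np.ones_like(zm, dtype=bool),
                                YEARS, ZONES)
    assert (table["burned_ha"] == 0).all()
    assert len(table) == len(YEARS) * 2


def test_single_object_area_and_patch_count():
    zm = simple_zone_map(60)
    px = [(r, c) for r in range(50) for c in range(20)]  # 1000 px, zone A
    table = annual_burned_table([fire_object(0, px, 1995)], zm,
                                np.ones_like(zm, dtype=bool), YEARS, ZONES)
    row = table[(table["zone"] == "A") & (table["year"] == 1995)]
    assert row["burned_ha"].iloc[0] == pytest.approx(90.0)
    assert row["n_patches"].iloc[0] == 1
    assert row["n_large_patches"].iloc[0] == 0


def test_zone_sums_match_pixel_tally_oracle(rng):
    zm = simple_zone_map(30)
    burnable = np.ones_like(zm, dtype=bool)
    objects = []
    for oid in range(30):
        n = int(rng.integers(1, 40))
        px = np.column_stack([rng.integers(0, 30, n),
                              rng.integers(0, 30, n)])
        px = np.unique(px, axis=0)
        objects.append(fire_object(oid, px, int(rng.choice(YEARS))))
    table = annual_burned_table(objects, zm, burnable, YEARS, ZONES)
    # oracle: accumulate pixel by pixel
    tally = {}
    for o in objects:
        for r, c in o.pixels:
            key = (ZONES[zm[r, c]], o.change_year)
            tally[key] = tally.get(key, 0.0) + 0.09
    for (zone, year), ha in tally.items():
        row = table[(table["zone"] == zone) & (table["year"] == year)]
        assert row["burned_ha"].iloc[0] == pytest.approx(ha)
    assert table["burned_ha"].sum() == pytest.approx(
        sum(o.n_pixels for o in objects) * 0.09)


def test_object_outside_zone_raster_is_an_error():
    zm = simple_zone_map(10)
    obj = fire_object(0, [(50, 50)], 1995)
    with pytest.raises(ValueError):
        annual_burned_table([obj], zm, np.ones_like(zm, dtype=bool),
                            YEARS, ZONES)


def test_zone_stats_constant_series():
    table = pd.DataFrame({
        "zone": "A", "year": YEARS, "burned_ha": 5.0,
        "burnable_ha": 100.0, "n_patches": 1, "n_large_patches": 0})
    zs = zone_stats(table)
    assert zs["mean_burned_ha"].iloc[0] == pytest.approx(5.0)
    assert zs["sd_burned_ha"].iloc[0] == pytest.approx(0.0)
    assert zs["paab_pct"].iloc[0] == pytest.approx(5.0)
    assert zs["fri_naive_yr"].iloc[0] == pytest.approx(20.0)


def test_zero_burnable_area_is_an_error():
    table = pd.DataFrame({
        "zone": "A", "year": YEARS, "burned_ha": 0.0,
        "burnable_ha": 0.0, "n_patches": 0, "n_large_patches": 0})
    with pytest.raises(ValueError):
        zone_stats(table)


# ---------------------------------------------------------------------------
# survival curve and FRI

def test_survival_is_one_when_nothing_burns():
    stack = np.zeros((10, 5, 5), dtype=bool)
    lags, surv = survival_curve(stack, np.ones((5, 5), dtype=bool))
    assert np.allclose(surv, 1.0)
    fit = fit_fri(lags, surv)
    assert fit.censored and math.isinf(fit.fri_yr)


def test_survival_matches_exhaustive_window_oracle():
    """Every pixel burned once mid-record: S(t) from direct enumeration."""
    T, mid = 11, 5
    stack = np.zeros((T, 4, 4), dtype=bool)
    stack[mid] = True
    burnable = np.ones((4, 4), dtype=bool)
    lags, surv = survival_curve(stack, burnable)
    for t in range(1, T):
        fracs = []
        for s in range(T - t + 1):
            burned_in_window = s <= mid < s + t
            fracs.append(0.0 if burned_in_window else 1.0)
        assert surv[t] == pytest.approx(np.mean(fracs))
    assert surv[0] == 1.0


def test_survival_non_increasing(rng):
    stack = rng.random((15, 20, 20)) < 0.02
    _, surv = survival_curve(stack, np.ones((20, 20), dtype=bool))
    assert (np.diff(surv) <= 1e-12).all()


def test_iid_burn_survival_matches_closed_form(rng):
    """With i.i.d. burn probability p, E[S(t)] = (1-p)^t."""
    p, T, n = 0.03, 25, 120
    stack = rng.random((T, n, n)) < p
    lags, surv = survival_curve(stack, np.ones((n, n), dtype=bool))
    expect = (1 - p) ** lags
    assert np.allclose(surv, expect, atol=0.01)


def test_fit_fri_recovers_exact_exponential():
    lags = np.arange(25)
    fit = fit_fri(lags, np.exp(-lags / 100.0))
    assert fit.fri_yr == pytest.approx(100.0, rel=1e-6)
    assert fit.residual_rmse < 1e-10


def test_fri_naive_consistency_with_published_paab():
    """1/burn-rate from the printed PAAB of the Taiga Plains (0.52 %/yr)
    lands within 5% of the published fitted interval (188 yr)."""
    row = reference.ECOZONE_STATS.set_index("zone").loc["Taiga Plains"]
    fri_naive = 100.0 / row["paab_pct"]
    assert fri_naive == pytest.approx(192.3, abs=0.1)
    assert abs(fri_naive - row["fri_yr"]) / row["fri_yr"] < 0.05


def test_fit_fri_rejects_invalid_survival():
    with pytest.raises(ValueError):
        fit_fri(np.arange(5), np.array([1.0, 0.9, 0.8, 0.0, 0.5]))


# ---------------------------------------------------------------------------
# trends

def test_theil_sen_exact_line():
    slope, pct = theil_sen(np.arange(1, 6), [1, 2, 3, 4, 5])
    assert slope == pytest.approx(1.0)
    assert pct == pytest.approx(100.0 * 1.0 / 3.0)


def test_theil_sen_worked_example():
    slope, _ = theil_sen(np.arange(1, 6), [0, 3, 1, 4, 2])
    assert slope == pytest.approx(0.5)


def test_theil_sen_matches_all_pairs_oracle(rng):
    for _ in range(100):
        n = int(rng.integers(3, 13))
        x = np.sort(rng.choice(np.arange(1980, 2020), n, replace=False))
        y = rng.normal(0, 10, n)
        slope, _ = theil_sen(x, y)
        pairs = [(y[j] - y[i]) / (x[j] - x[i])
                 for i, j in itertools.combinations(range(n), 2)]
        assert slope == pytest.approx(np.median(pairs))


def test_theil_sen_scale_equivariance(rng):
    x = np.arange(2000, 2012)
    y = rng.normal(5, 2, 12)
    s1, _ = theil_sen(x, y)
    s2, _ = theil_sen(x, 3.5 * y)
    assert s2 == pytest.approx(3.5 * s1)


def test_theil_sen_needs_three_points():
    with pytest.raises(ValueError):
        theil_sen([1, 2], [1.0, 2.0])


def test_mann_kendall_monotone_extremes():
    res = mann_kendall([1.0, 2.0, 3.0, 4.0], method="normal")
    assert res.s_statistic == 6  # maximal for n = 4
    res = mann_kendall([5.0, 4.0, 3.0, 2.0, 1.0], method="normal")
    assert res.s_statistic == -10


def test_mann_kendall_invariant_under_monotone_transform(rng):
    y = rng.normal(0, 1, 15)
    r1 = mann_kendall(y, method="normal")
    r2 = mann_kendall(np.exp(y), method="normal")
    assert r1.s_statistic == r2.s_statistic
    assert r1.p_value == pytest.approx(r2.p_value)


def test_mann_kendall_tie_corrected_variance():
    y = np.array([1.0, 2.0, 2.0, 3.0])
    res = mann_kendall(y, method="normal")
    n = 4
    expect = (n * (n - 1) * (2 * n + 5) - 2 * 1 * 9) / 18.0
    assert res.var_s == pytest.approx(expect)


def test_mann_kendall_degenerate_all_tied():
    res = mann_kendall([2.0] * 6)
    assert res.degenerate and res.p_value == 1.0 and res.s_statistic == 0


def test_mann_kendall_exact_null_via_enumeration():
    """Exact p for n = 5 equals full enumeration over all 120 orderings."""
    y = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
    res = mann_kendall(y, method="exact")
    s_obs = res.s_statistic
    count = 0
    for perm in itertools.permutations(range(5)):
        vals = np.array(perm, dtype=float)
        s = sum(np.sign(vals[j] - vals[i])
                for i, j in itertools.combinations(range(5), 2))
        if abs(s) >= abs(s_obs):
            count += 1
    assert res.p_value == pytest.approx(count / math.factorial(5))


def test_trend_test_combines_slope_and_significance():
    res = trend_test(np.arange(1985, 2016), np.arange(31) * 2.0 + 5.0,
                     method="normal")
    assert res.slope == pytest.approx(2.0)
    assert res.significant


def test_published_slope_percentages():
    """Printed significant slopes reproduce the printed percent-of-mean
    values at printed precision."""
    stats = reference.ECOZONE_STATS.set_index("zone")
    am = slope_percent(-20.6, stats.loc["Atlantic Maritime",
                                        "mean_burned_ha"])
    mc = slope_percent(709.3, stats.loc["Montane Cordillera",
                                        "mean_burned_ha"])
    assert round(am, 1) == -2.4
    assert round(mc, 1) == 2.4


# ---------------------------------------------------------------------------
# patch sizes, large-patch trends, epochs

def test_patch_distribution_all_small():
    table, count_share, area_share = patch_size_distribution([1.0, 5.0, 50.0])
    assert count_share == 0.0 and area_share == 0.0
    assert table["n_patches"].sum() == 3


def test_patch_distribution_hand_arithmetic():
    areas = [1.0] * 97 + [563.0] * 3
    _, count_share, area_share = patch_size_distribution(areas)
    assert count_share == pytest.approx(3.0)
    assert area_share == pytest.approx(100 * 1689 / 1786, abs=0.01)


def test_exact_boundary_value_falls_in_lower_class():
    table, count_share, _ = patch_size_distribution([200.0])  # = 2 km^2
    km2 = table[(table["class_lo_km2"] == 2.0)]
    assert km2["n_patches"].iloc[0] == 1
    assert count_share == 0.0  # strict > for the large-patch share


def test_empty_object_set_gives_zeros():
    table, count_share, area_share = patch_size_distribution([])
    assert table["n_patches"].sum() == 0
    assert count_share == 0.0 and area_share == 0.0


def test_large_patch_trend_constant_counts():
    table = pd.DataFrame({"zone": "A", "year": YEARS, "burned_ha": 1.0,
                          "burnable_ha": 10.0, "n_patches": 3,
                          "n_large_patches": 2})
    res = large_patch_trend(table)
    assert res.slope == pytest.approx(0.0)
    assert not res.significant


def test_large_patch_trend_linear_counts():
    table = pd.DataFrame({"zone": "A", "year": YEARS, "burned_ha": 1.0,
                          "burnable_ha": 10.0, "n_patches": 3,
                          "n_large_patches": np.arange(1, 11)})
    res = large_patch_trend(table)
    assert res.slope == pytest.approx(1.0)
    assert res.s_statistic == 45  # maximal for n = 10
    assert res.significant


def test_epoch_edges_final_epoch_absorbs_remainder():
    assert epoch_edges(1985, 2015, 5) == [
        (1985, 1989), (1990, 1994), (1995, 1999),
        (2000, 2004), (2005, 2009), (2010, 2015)]


def test_grid_epoch_no_fires_all_zero():
    stack = np.zeros((10, 20, 20), dtype=bool)
    out = grid_epoch_summary(stack, np.ones((20, 20), dtype=bool),
                             np.arange(1985, 1995), pixel_size_m=1000.0,
                             cell_km=10, epoch_yr=5)
    assert (out["pct_burned"] == 0).all()


def test_grid_epoch_fully_burned_cell_is_100_percent():
    # 20x20 px at 1 km/px, 10 km cells -> 2x2 cells of 10x10 px
    stack = np.zeros((10, 20, 20), dtype=bool)
    stack[2, :10, :10] = True
    out = grid_epoch_summary(stack, np.ones((20, 20), dtype=bool),
                             np.arange(1985, 1995), pixel_size_m=1000.0,
                             cell_km=10, epoch_yr=5)
    first = out[(out["cell_row"] == 0) & (out["cell_col"] == 0)
                & (out["epoch_start"] == 1985)]
    assert first["pct_burned"].iloc[0] == pytest.approx(100.0)
    other = out[(out["cell_row"] == 1) & (out["epoch_start"] == 1985)]
    assert (other["pct_burned"] == 0).all()


def test_grid_epoch_matches_pixel_tally_oracle(rng):
    stack = rng.random((10, 25, 25)) < 0.03
    burnable = rng.random((25, 25)) < 0.8
    years = np.arange(1985, 1995)
    out = grid_epoch_summary(stack, burnable, years, pixel_size_m=1000.0,
                             cell_km=10, epoch_yr=5)
    cell_px = 10
    for _, row in out.iterrows():
        r0, c0 = int(row["cell_row"]) * cell_px, int(row["cell_col"]) * cell_px
        cell_burnable = burnable[r0:r0 + cell_px, c0:c0 + cell_px]
        sel = (years >= row["epoch_start"]) & (years <= row["epoch_end"])
        burned = stack[sel][:, r0:r0 + cell_px, c0:c0 + cell_px].any(axis=0)
        burned &= cell_burnable
        if cell_burnable.sum() == 0:
            assert math.isnan(row["pct_burned"])
        else:
            assert row["pct_burned"] == pytest.approx(
                100.0 * burned.sum() / cell_burnable.sum())


def test_zero_burnable_cell_is_not_applicable():
    burnable = np.zeros((20, 20), dtype=bool)
    burnable[:10, :10] = True
    stack = np.zeros((10, 20, 20), dtype=bool)
    out = grid_epoch_summary(stack, burnable, np.arange(1985, 1995),
                             pixel_size_m=1000.0, cell_km=10, epoch_yr=5)
    empty = out[(out["cell_row"] == 1) & (out["cell_col"] == 1)]
    assert empty["pct_burned"].isna().all()
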