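"""Accrual filters, rates, saturation assignment, and the asymptotic fit."""

import numpy as np
import pandas as pd
import pytest
import xarray as xr

from mocsat import accrual, gridmap, rf_model, synthgen
from mocsat.accrual import (
    REASON_ANNUAL,
    REASON_DEPTH,
    REASON_ONETIME,
    REASON_TEXTURE,
    REASON_UNKNOWN,
    AsymptoticFit,
    accrual_rate,
    accrual_sensitivity,
    assign_saturation,
    filter_accrual,
    fit_asymptotic,
    potential_accrual_map,
    standardize_depth,
)
from mocsat.capacity import BoundaryFit

FITS = {
    "HM": BoundaryFit("HM", 0.95, 0.86, 0.8, 0.9, 100, 1),
    "LM": BoundaryFit("LM", 0.95, 0.48, 0.4, 0.5, 50, 1),
}


def test_filters_reject_with_exact_reasons(accrual_data):
    records, _ = accrual_data
    kept, rejected = filter_accrual(records)
    assert len(kept) + len(rejected) == len(records)
    # every constructed violation is rejected for its constructed reason
    expected = {
        "depth": REASON_DEPTH,
        "annual": REASON_ANNUAL,
        "onetime": REASON_ONETIME,
        "unknown": REASON_UNKNOWN,
        "texture": REASON_TEXTURE,
    }
    by_id = rejected.set_index("record_id")
    violators = records[records.get("violation").notna()]
    assert len(rejected) == len(violators)
    for _, row in violators.iterrows():
        assert by_id.loc[row["record_id"], "reason"] == expected[row["violation"]]
    assert not kept["record_id"].str.startswith("X").any()


def test_differing_cs_same_texture_class_averaged():
    df = pd.DataFrame(
        {
            "depth_cm": [30.0],
            "cs_pct": [30.0],
            "cs_pct_initial": [30.0],
            "cs_pct_final": [34.0],
            "texture_class_initial": ["loam"],
            "texture_class_final": ["loam"],
        }
    )
    kept, rejected = filter_accrual(df)
    assert rejected.empty
    assert kept.loc[0, "cs_pct"] == pytest.approx(32.0)


def test_depth_standardization():
    shallow = [(0, 0.0), (15, 20.0), (30, 36.0)]
    deep = [(0, 0.0), (20, 25.0), (39, 45.0)]
    s1, s2, common = standardize_depth(shallow, deep)
    assert common == 30.0
    assert s1 == pytest.approx(36.0)
    # deeper profile interpolated at 30 cm
    assert s2 == pytest.approx(25.0 + (45.0 - 25.0) * 10.0 / 19.0)

    a, b, c = standardize_depth(shallow, shallow)
    assert (a, b, c) == (36.0, 36.0, 30.0)

    # linear cumulative profile truncated to half depth holds half the stock
    lin = [(0, 0.0), (40, 40.0)]
    half = [(0, 0.0), (20, 99.0)]
    s1, _, common = standardize_depth(lin, half)
    assert common == 20.0 and s1 == pytest.approx(20.0)

    with pytest.raises(ValueError, match="non-overlapping"):
        standardize_depth([(30, 1.0), (40, 2.0)], [(0, 0.0), (20, 1.0)])


def test_accrual_rate_and_antisymmetry():
    assert accrual_rate(30.0, 36.0, 12.0) == pytest.approx(0.5)
    assert accrual_rate(30.0, 30.0, 5.0) == 0.0
    assert accrual_rate(40.0, 30.0, 10.0) == pytest.approx(-1.0)
    assert accrual_rate(10.0, 25.0, 5.0) == -accrual_rate(25.0, 10.0, 5.0)
    with pytest.raises(ValueError):
        accrual_rate(1.0, 2.0, 0.0)


def test_assign_saturation_measured_stock():
    df = pd.DataFrame(
        {
            "depth_cm": [30.0],
            "cs_pct": [31.0],
            "mineral_type": ["HM"],
            "bd_g_cm3": [1.0],
            "initial_stock_t_ha": [40.0],
            "moc_initial_stock_t_ha": [20.0],
        }
    )
    # MOC_max stock = 0.86 * 31 * 1.0 * 0.3 * 10 = 79.98 t/ha
    out = assign_saturation(df, FITS)
    assert out.loc[0, "pct_saturation"] == pytest.approx(100 * 20.0 / 79.98)


def test_assign_saturation_recovers_generator_truth(accrual_data):
    records, truth = accrual_data
    kept, _ = filter_accrual(records)
    cfg = synthgen.GeneratorConfig(seed=11)
    gen_fits = {
        "HM": BoundaryFit("HM", 0.95, cfg.slope_hm, 0, 1, 10, 1),
        "LM": BoundaryFit("LM", 0.95, cfg.slope_lm, 0, 1, 10, 1),
    }
    out = assign_saturation(kept, gen_fits)
    merged = out.merge(truth, on="record_id")
    np.testing.assert_allclose(
        merged["pct_saturation"].to_numpy() / 100.0, merged["sat_true"].to_numpy(), rtol=1e-9
    )
    assert merged.loc[merged["sat_true"] > 1.0, "oversaturated_flag"].all()


def test_assign_saturation_missing_bd_fatal():
    df = pd.DataFrame(
        {"depth_cm": [30.0], "cs_pct": [31.0], "mineral_type": ["HM"], "bd_g_cm3": [np.nan]}
    )
    with pytest.raises(ValueError, match="bulk density"):
        assign_saturation(df, FITS)


def test_assign_saturation_via_soc_cs_model(profiles):
    model = rf_model.train_ensemble(profiles, "accrual", n_members=3, trees=30, seed=0)
    df = pd.DataFrame(
        {
            "depth_cm": [30.0, 30.0],
            "cs_pct": [40.0, 60.0],
            "mineral_type": ["HM", "HM"],
            "bd_g_cm3": [1.3, 1.3],
            "initial_stock_t_ha": [60.0, 90.0],
            "moc_initial_stock_t_ha": [np.nan, np.nan],
        }
    )
    out = assign_saturation(df, FITS, soc_cs_model=model)
    assert out["pct_saturation"].between(0, 300).all()
    with pytest.raises(ValueError, match="SOC\\+CS model"):
        assign_saturation(df, FITS)


def test_noiseless_fit_recovers_parameters_to_1e4():
    rng = np.random.default_rng(0)
    s = rng.uniform(0.0, 1.1, 60)
    truth = (0.05, 1.6, 1.5)
    r = truth[0] + (truth[1] - truth[0]) * np.exp(-np.exp(truth[2]) * s)
    fit = fit_asymptotic(s, r, tau="mean")
    assert fit.asym == pytest.approx(truth[0], abs=1e-4)
    assert fit.r0 == pytest.approx(truth[1], abs=1e-4)
    assert fit.lrc == pytest.approx(truth[2], abs=1e-4)
    assert fit.r2 == pytest.approx(1.0)


def test_constant_rates_degenerate_flat_fit():
    fit = fit_asymptotic(np.linspace(0, 1, 12), np.full(12, 0.7))
    assert fit.asym == fit.r0 == pytest.approx(0.7)
    assert fit.predict(0.3) == pytest.approx(0.7)


def test_too_few_points_fatal():
    with pytest.raises(ValueError, match=">= 10"):
        fit_asymptotic([0.1, 0.5], [1.0, 0.5])


def test_quantile_fits_bracket_mean_curve(accrual_data):
    records, truth = accrual_data
    s = truth["sat_true"].to_numpy()
    r = truth["rate_obs"].to_numpy()
    mean_fit = fit_asymptotic(s, r, tau="mean")
    lo = fit_asymptotic(s, r, tau=0.1)
    hi = fit_asymptotic(s, r, tau=0.9)
    grid = np.linspace(0.05, 1.0, 12)
    assert np.all(lo.predict(grid) <= hi.predict(grid) + 1e-9)
    margin = 0.05 * np.ptp(r)
    assert np.all(lo.predict(grid) <= mean_fit.predict(grid) + margin)
    assert np.all(mean_fit.predict(grid) <= hi.predict(grid) + margin)


def test_saturation_explains_more_variance_than_initial_soc(accrual_data):
    records, truth = accrual_data
    kept, _ = filter_accrual(records)
    merged = kept.merge(truth, on="record_id")
    s = merged["sat_true"].to_numpy()
    r = merged["rate_obs"].to_numpy()
    r2_sat = fit_asymptotic(s, r, tau="mean").r2
    soc = merged["initial_stock_t_ha"].to_numpy()
    coef = np.polyfit(soc, r, 1)
    resid = r - np.polyval(coef, soc)
    r2_soc = 1.0 - resid.var() / r.var()
    assert r2_sat > r2_soc


def test_sensitivity_refits(accrual_data):
    records, truth = accrual_data
    kept, _ = filter_accrual(records)
    merged = kept.merge(truth, on="record_id")
    merged["pct_saturation"] = 100 * merged["sat_true"]
    merged["rate_t_ha_yr"] = merged["rate_obs"]
    rng = np.random.default_rng(0)
    drop10 = pd.Series(rng.random(len(merged)) < 0.1, index=merged.index)
    out = accrual_sensitivity(
        merged,
        {
            "nothing": lambda df: pd.Series(False, index=df.index),
            "random_10pct": lambda df: drop10,
            "andisols": lambda df: df["soil_order"] == "Andisol",
        },
    )
    base = out[out["exclusion"] == "none"].iloc[0]
    nothing = out[out["exclusion"] == "nothing"].iloc[0]
    assert nothing["asym"] == base["asym"] and nothing["lrc"] == base["lrc"]
    assert out["declining"].all()  # negative trend robust to exclusions
    rand = out[out["exclusion"] == "random_10pct"].iloc[0]
    assert abs(rand["d_r0"]) < 0.5 * base["r0"]
    with pytest.raises(ValueError, match="empties"):
        accrual_sensitivity(merged, {"all": lambda df: pd.Series(True, index=df.index)})


def test_potential_accrual_toy_grid_hand_computed():
    ds = xr.Dataset(coords={"lat": [0.25, 0.75], "lon": [0.25, 0.75]})
    stack = gridmap.GridStack(ds, resolution_deg=0.5)
    stack.set_layer("organic_fraction", np.zeros((2, 2)))
    stack.set_layer(
        "land_cover", np.full((2, 2), float(gridmap.LANDCOVER_CLASSES.index("cropland")))
    )
    crop = np.array([[1.0, 1.0], [1.0, 0.0]])
    stack.set_layer("cropland", crop)
    sat = xr.DataArray(
        np.array([[10.0, 50.0], [90.0, 50.0]]),
        coords={"lat": stack.lat, "lon": stack.lon},
        dims=("lat", "lon"),
    )
    fit = AsymptoticFit(asym=0.2, r0=1.8, lrc=np.log(4.0), tau="mean", n=10, r2=1.0, sse=0.0)
    rate_map, total = potential_accrual_map(sat, fit, stack)
    rates = rate_map.to_numpy()
    assert np.isnan(rates[1, 1])  # not cropland
    areas_ha = gridmap.cell_area_km2(stack.lat, 0.5) * 100.0
    expected = (
        fit.predict(0.1) * areas_ha[0]
        + fit.predict(0.5) * areas_ha[0]
        + fit.predict(0.9) * areas_ha[1]
    ) / 1e9
    assert total == pytest.approx(expected, rel=1e-9)

    # uniform saturation: total = rate at that saturation x cropland area
    uniform = xr.DataArray(
        np.full((2, 2), 50.0), coords={"lat": stack.lat, "lon": stack.lon}, dims=("lat", "lon")
    )
    _, total_u = potential_accrual_map(uniform, fit, stack)
    crop_area_ha = areas_ha[0] * 2 + areas_ha[1]
    assert total_u == pytest.approx(fit.predict(0.5) * crop_area_ha / 1e9, rel=1e-9)
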