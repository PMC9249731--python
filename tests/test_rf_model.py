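"""Ensemble mechanics, partial dependence vs brute force, and the CV designs."""

import numpy as np
import pandas as pd
import pytest
from sklearn.ensemble import RandomForestRegressor

from mocsat import rf_model, synthgen
from mocsat.rf_model import (
    buffered_loo_cv,
    conditional_partial_dependence,
    encode_features,
    haversine_km,
    holdout_cv_by_group,
    partial_dependence,
    permutation_importance,
    predict_with_interval,
    train_ensemble,
)


def brute_force_pd(model, variable, grid, X_bg):
    """Eq.-style double loop: average the ensemble-mean prediction row by row."""
    j = list(model.feature_spec).index(variable)
    out = []
    for g in grid:
        acc = 0.0
        for i in range(X_bg.shape[0]):
            row = X_bg[i].copy()
            row[j] = g
            acc += float(model.predict_mean(row[None, :])[0])
        out.append(acc / X_bg.shape[0])
    return np.asarray(out)


def test_deterministic_signal_learned(toy_profiles):
    df = toy_profiles.copy()
    df["moc_g_kg"] = 0.5 * df["cs_pct"]
    model = train_ensemble(df, ("cs_pct",), n_members=4, trees=50, seed=0, min_cases=10)
    assert model.mean_r2 > 0.95


def test_attribution_r2_within_noise_band(attribution_model):
    # generator noise share tuned so the POC feature set explains ~60%
    assert 0.5 <= attribution_model.mean_r2 <= 0.8


def test_seed_reproduces_splits_and_metrics_bitwise(toy_profiles):
    kw = dict(feature_spec=("cs_pct", "mat_c"), n_members=3, trees=20, seed=5, min_cases=10)
    a = train_ensemble(toy_profiles, **kw)
    b = train_ensemble(toy_profiles, **kw)
    for ma, mb in zip(a.members, b.members):
        np.testing.assert_array_equal(ma.train_idx, mb.train_idx)
        np.testing.assert_array_equal(ma.test_idx, mb.test_idx)
        assert ma.mse == mb.mse and ma.r2 == mb.r2 and ma.mae == mb.mae


def test_too_few_complete_cases_fatal(toy_profiles):
    with pytest.raises(ValueError, match="complete cases"):
        train_ensemble(toy_profiles.head(10), ("cs_pct",), n_members=2, trees=10, seed=0)


def test_unseen_category_level_fatal(toy_profiles):
    df = toy_profiles.copy()
    df.loc[df.index[0], "vegetation"] = "mangrove"
    with pytest.raises(ValueError, match="mangrove"):
        encode_features(df, ("cs_pct", "vegetation"))


def test_single_member_interval_collapses(toy_profiles):
    model = train_ensemble(
        toy_profiles, ("cs_pct", "mat_c"), n_members=1, trees=20, seed=0, min_cases=10
    )
    pred = predict_with_interval(model, toy_profiles.head(5))
    np.testing.assert_array_equal(pred["q05"], pred["mean"])
    np.testing.assert_array_equal(pred["q95"], pred["mean"])


def test_constant_target_constant_prediction(toy_profiles):
    df = toy_profiles.copy()
    df["moc_g_kg"] = 7.0
    model = train_ensemble(df, ("cs_pct",), n_members=3, trees=10, seed=0, min_cases=10)
    pred = predict_with_interval(model, df.head(4))
    np.testing.assert_allclose(pred["mean"], 7.0)
    np.testing.assert_allclose(pred["q05"], 7.0)


def test_partial_dependence_equals_brute_force(attribution_model):
    model = attribution_model
    X_bg = model.X[:40]
    grid = np.linspace(5, 80, 5)
    ours = partial_dependence(model, "cs_pct", grid, background=X_bg)
    brute = brute_force_pd(model, "cs_pct", grid, X_bg)
    np.testing.assert_allclose(ours.pd_values, brute, atol=1e-12)


def test_partial_dependence_grid_and_background_validation(attribution_model):
    with pytest.raises(ValueError, match="strictly increasing"):
        partial_dependence(attribution_model, "cs_pct", [1.0, 1.0, 2.0])
    with pytest.raises(ValueError, match="background"):
        partial_dependence(
            attribution_model, "cs_pct", [1.0, 2.0], background=np.empty((0, 6))
        )


def test_additive_oracle_pd_recovers_component_shape():
    """For y = g(x0) + h(x1), the PD of x0 tracks g up to a constant."""
    rng = np.random.default_rng(1)
    n = 400
    df = pd.DataFrame({"a": rng.uniform(0, 10, n), "b": rng.uniform(0, 10, n)})
    df["moc_g_kg"] = 2.0 * df["a"] + np.sin(df["b"])
    model = train_ensemble(df, ("a", "b"), n_members=4, trees=60, seed=0, min_cases=10)
    grid = np.linspace(1, 9, 9)
    pdep = partial_dependence(model, "a", grid)
    centred = pdep.pd_values - pdep.pd_values.mean()
    expected = 2.0 * grid - (2.0 * grid).mean()
    np.testing.assert_allclose(centred, expected, atol=0.8)


def test_poc_response_saturates(attribution_model):
    """The MOC-POC partial dependence flattens at high POC (Langmuir link)."""
    model = attribution_model
    j = list(model.feature_spec).index("poc_g_kg")
    poc = model.X[:, j]
    low = np.quantile(poc, [0.05, 0.30])
    high = np.quantile(poc, [0.70, 0.95])
    pd_low = partial_dependence(model, "poc_g_kg", low)
    pd_high = partial_dependence(model, "poc_g_kg", high)
    slope_low = np.diff(pd_low.pd_values)[0] / np.diff(low)[0]
    slope_high = np.diff(pd_high.pd_values)[0] / np.diff(high)[0]
    assert slope_high < 0.2 * slope_low


def test_conditional_pd_breakpoints_default_to_median_and_q3(attribution_model):
    model = attribution_model
    j = list(model.feature_spec).index("poc_g_kg")
    poc = model.X[:, j]
    grid = np.linspace(poc.min() + 0.1, np.quantile(poc, 0.9), 4)
    cpd = conditional_partial_dependence(model, "mat_c", np.linspace(0, 25, 4))
    assert set(cpd) == {"L", "M", "H"}
    lo = float(np.median(poc))
    assert cpd["L"].condition == "poc_g_kg:L"
    # regime sizes follow the median/Q3 split
    assert np.isclose(np.median(poc), lo)


def test_temperature_sensitivity_concentrated_at_low_poc(attribution_model):
    grid = np.linspace(0, 25, 6)
    cpd = conditional_partial_dependence(attribution_model, "mat_c", grid)
    slope = {
        k: abs(np.polyfit(grid, v.pd_values, 1)[0]) for k, v in cpd.items()
    }
    assert slope["L"] > slope["H"]


def test_conditional_pd_constant_condition_variable():
    rng = np.random.default_rng(0)
    n = 120
    df = pd.DataFrame(
        {
            "a": rng.uniform(0, 10, n),
            "poc_g_kg": 5.0,
            "moc_g_kg": rng.uniform(0, 10, n),
        }
    )
    model = train_ensemble(df, ("a", "poc_g_kg"), n_members=2, trees=10, seed=0, min_cases=10)
    cpd = conditional_partial_dependence(model, "a", np.linspace(1, 9, 4))
    np.testing.assert_array_equal(cpd["L"].pd_values, cpd["M"].pd_values)
    np.testing.assert_array_equal(cpd["M"].pd_values, cpd["H"].pd_values)


def test_pure_noise_feature_ranked_last(profiles):
    df = profiles.head(500).copy()
    rng = np.random.default_rng(0)
    df["noise_feature"] = rng.standard_normal(len(df))
    model = train_ensemble(
        df,
        ("cs_pct", "soc_g_kg", "noise_feature"),
        n_members=4,
        trees=50,
        seed=0,
    )
    imp = permutation_importance(model, seed=0)
    assert imp.iloc[-1]["feature"] == "noise_feature"
    assert abs(imp.iloc[-1]["delta_mse"]) < 0.1 * imp.iloc[0]["delta_mse"]


def test_dominant_cs_effect_ranked_first():
    cfg = synthgen.GeneratorConfig(
        seed=2, n_profiles=700, sat_map_exponent=0.0, langmuir_k_base=50.0
    )
    prof, _ = synthgen.generate_profiles(cfg)
    model = train_ensemble(prof, "attribution", n_members=4, trees=50, seed=0)
    imp = permutation_importance(model, seed=0)
    assert imp.iloc[0]["feature"] == "cs_pct"


def test_permuted_target_sanity_oracle(attribution_model):
    """Permuting the target inflates MSE by roughly the explained variance
    scale — far above any single feature's increase."""
    model = attribution_model
    rng = np.random.default_rng(0)
    var = float(np.var(model.y))
    deltas = []
    for m in model.members:
        Xt, yt = model.X[m.test_idx], model.y[m.test_idx]
        pred = m.model.predict(Xt)
        base = float(np.mean((pred - yt) ** 2))
        perm = float(np.mean((pred - rng.permutation(yt)) ** 2))
        deltas.append(perm - base)
    delta = np.mean(deltas)
    assert 0.5 * var < delta < 3.0 * var
    imp = permutation_importance(model, seed=0)
    assert delta > imp["delta_mse"].max()


def test_collinear_duplicate_importance_never_negative(profiles):
    df = profiles.head(400).copy()
    df["cs_dup"] = df["cs_pct"]
    model = train_ensemble(df, ("cs_pct", "cs_dup", "mat_c"), n_members=4, trees=40, seed=0)
    imp = permutation_importance(model, seed=0).set_index("feature")["delta_mse"]
    floor = -0.05 * abs(imp.max())
    assert imp["cs_pct"] > floor and imp["cs_dup"] > floor


def test_haversine_reference_distances():
    assert haversine_km(10.0, 20.0, 10.0, 20.0) == 0.0
    assert haversine_km(0.0, 0.0, 0.0, 180.0) == pytest.approx(np.pi * 6371.0, rel=1e-6)
    assert haversine_km(0.0, 0.0, 0.0, 1.0) == pytest.approx(6371.0 * np.pi / 180.0, rel=1e-6)


def test_buffered_loo_radius_zero_is_plain_loo(profiles):
    """With distinct coordinates, a 0 km buffer trains on exactly the
    other n-1 points — plain leave-one-out."""
    df = profiles.head(60).copy()
    res = buffered_loo_cv(
        df, "prediction", radii_km=[0.0], seed=4, trees=25, max_test_points=60
    )
    X = encode_features(df, rf_model.FEATURE_SPECS["prediction"])
    y = df["moc_g_kg"].to_numpy(float)
    preds = []
    for ti in range(len(df)):
        mask = np.ones(len(df), bool)
        mask[ti] = False
        m = RandomForestRegressor(n_estimators=25, random_state=4 + ti, n_jobs=1)
        m.fit(X[mask], y[mask])
        preds.append(float(m.predict(X[ti : ti + 1])[0]))
    preds = np.asarray(preds)
    sst = float(np.sum((y - y.mean()) ** 2))
    plain_r2 = 1.0 - float(np.sum((y - preds) ** 2)) / sst
    assert res.r2[0] == pytest.approx(plain_r2, abs=1e-12)
    assert res.skipped == 0


def test_buffered_loo_flat_without_spatial_structure(profiles):
    df = profiles.head(150)
    res = buffered_loo_cv(
        df, "prediction", radii_km=[0, 400, 800], seed=0, trees=25, max_test_points=40
    )
    assert res.trend_pvalue > 0.05


def test_buffered_loo_declines_under_spatial_autocorrelation():
    cfg = synthgen.GeneratorConfig(
        seed=6, n_profiles=150, spatial_range_km=3000.0, spatial_noise_sd=0.8
    )
    prof, _ = synthgen.generate_profiles(cfg)
    res = buffered_loo_cv(
        prof, "prediction", radii_km=[0, 1500, 3000], seed=0, trees=25, max_test_points=40
    )
    assert res.r2[0] > res.r2[-1]


def test_holdout_cv_by_soil_order(profiles):
    df = profiles.head(600)
    out = holdout_cv_by_group(df, "soil_order", "prediction", seed=0, trees=30)
    assert len(out) >= 2
    assert out["r2"].between(-1, 1).all()


def test_holdout_detects_shifted_regime(profiles):
    df = profiles.head(600).copy()
    shifted = df["soil_order"] == "Mollisol"
    df.loc[shifted, "moc_g_kg"] += 60.0  # an out-of-regime group
    out = holdout_cv_by_group(df, "soil_order", "prediction", seed=0, trees=30).set_index("group")
    assert out.loc["Mollisol", "r2"] < out.drop("Mollisol")["r2"].min()


def test_holdout_single_group_fatal(profiles):
    df = profiles.head(100).copy()
    df["soil_order"] = "Mollisol"
    with pytest.raises(ValueError):
        holdout_cv_by_group(df, "soil_order", "prediction", seed=0, trees=10)
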