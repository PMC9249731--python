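"""Carbon-accrual synthesis and the asymptotic accrual-vs-saturation model.

Accrual records pair initial and final topsoil carbon stocks around a
management intervention (improved agriculture, land-use change, litter
addition, revegetation of mine soils) or along a chronosequence.  After
quality filtering, the accrual rate (t C ha-1 yr-1) is (final - initial) /
duration, and each record's initial mineralogical %C saturation is its
initial MOC stock over its MOC_max stock (slope x CS x BD over the studied
depth).  When MOC was not measured, it is imputed from SOC and CS with the
compact random-forest spec.

The central relation is a three-parameter asymptotic regression

    rate(s) = asym + (r0 - asym) * exp(-exp(lrc) * s)

with s the saturation as a *fraction*: r0 is the rate of a carbon-free
mineral matrix, asym the rate as saturation grows large, and exp(lrc) the
decay constant per unit saturation.  The mean curve is fitted by nonlinear
least squares with a deterministic multi-start grid (emulating a
self-starting routine); the 10th and 90th quantile envelopes use the same
functional form under the pinball loss.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import xarray as xr
from scipy import optimize

from .capacity import BoundaryFit
from .gridmap import GridStack, _area_grid_m2, _get_mask
from .rf_model import EnsembleModel, encode_features

logger = logging.getLogger("mocsat")

MIN_DEPTH_CM = 15.0
MAX_ONETIME_AMENDMENT_T_HA = 20.0

#: kg C m-2  ->  t C ha-1
KG_M2_TO_T_HA = 10.0

REASON_DEPTH = "depth < 15 cm"
REASON_ANNUAL = "annual organic amendment"
REASON_ONETIME = "one-time amendment > 20 t/ha without control"
REASON_UNKNOWN = "amendment of unknown intensity"
REASON_TEXTURE = "initial and final texture classes differ"


def filter_accrual(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the synthesis quality filters; every failure gets a reason.

    Rejections: studied depth shallower than 15 cm; organic amendments that
    were annual, a one-time application above 20 t ha-1 without a control
    plot, or of unknown intensity; initial/final texture-class changes.
    When initial and final CS differ but the texture class matches, their
    mean is used.
    """
    df = records.copy()
    reasons = pd.Series("", index=df.index, dtype=object)

    def _mark(mask, reason: str) -> None:
        fresh = np.asarray(mask, bool) & (reasons == "").to_numpy()
        reasons.iloc[fresh] = reason

    _mark(df["depth_cm"] < MIN_DEPTH_CM, REASON_DEPTH)
    if "amendment_annual" in df.columns:
        _mark(df["amendment_annual"].fillna(False).astype(bool), REASON_ANNUAL)
    if "amendment_t_ha" in df.columns:
        onetime = df["amendment_t_ha"].fillna(0.0) > MAX_ONETIME_AMENDMENT_T_HA
        no_control = ~df.get("has_control", pd.Series(True, index=df.index)).fillna(False).astype(bool)
        _mark(onetime & no_control, REASON_ONETIME)
        if "amendment_applied" in df.columns:
            unknown = df["amendment_applied"].fillna(False).astype(bool) & df["amendment_t_ha"].isna()
            _mark(unknown, REASON_UNKNOWN)
    if {"texture_class_initial", "texture_class_final"} <= set(df.columns):
        both = df["texture_class_initial"].notna() & df["texture_class_final"].notna()
        _mark(both & (df["texture_class_initial"] != df["texture_class_final"]), REASON_TEXTURE)

    kept = df[reasons == ""].copy()
    rejected = df[reasons != ""].copy()
    rejected["reason"] = reasons[reasons != ""]

    if {"cs_pct_initial", "cs_pct_final"} <= set(kept.columns):
        both = kept["cs_pct_initial"].notna() & kept["cs_pct_final"].notna()
        kept.loc[both, "cs_pct"] = 0.5 * (
            kept.loc[both, "cs_pct_initial"] + kept.loc[both, "cs_pct_final"]
        )
    logger.info("accrual filters: %d kept, %d rejected", len(kept), len(rejected))
    return kept.reset_index(drop=True), rejected.reset_index(drop=True)


def standardize_depth(
    initial_profile: Sequence[tuple[float, float]],
    final_profile: Sequence[tuple[float, float]],
) -> tuple[float, float, float]:
    """Truncate paired cumulative-stock profiles to the shallower maximum.

    Each profile is a sequence of (depth_cm, cumulative stock t C ha-1)
    points starting at the surface; stocks are interpolated linearly within
    reported depths.  Returns (initial stock, final stock, common depth).
    """
    def _parse(profile):
        arr = np.asarray(profile, dtype=float)
        order = np.argsort(arr[:, 0])
        return arr[order, 0], arr[order, 1]

    d1, s1 = _parse(initial_profile)
    d2, s2 = _parse(final_profile)
    common = min(d1[-1], d2[-1])
    if common <= max(d1[0], d2[0]):
        raise ValueError("non-overlapping depth supports")
    stock1 = float(np.interp(common, d1, s1))
    stock2 = float(np.interp(common, d2, s2))
    return stock1, stock2, float(common)


def accrual_rate(initial_stock, final_stock, duration_yr):
    """(final - initial) / duration in t C ha-1 yr-1; losses are negative."""
    duration = np.asarray(duration_yr, dtype=float)
    if np.any(duration <= 0):
        raise ValueError("duration must be positive")
    out = (np.asarray(final_stock, float) - np.asarray(initial_stock, float)) / duration
    return float(out) if out.ndim == 0 else out


def assign_saturation(
    records: pd.DataFrame,
    fits: Mapping[str, BoundaryFit],
    soc_cs_model: EnsembleModel | None = None,
) -> pd.DataFrame:
    """Initial %C saturation of each accrual record.

    MOC_max stock (t ha-1) = slope(mineral type) x CS x BD x depth x 10;
    the initial MOC stock is the measured one when present, otherwise the
    MOC concentration is predicted from initial SOC and CS with the compact
    RF model and converted with the same BD and depth.  Values above 100%
    are retained and flagged.
    """
    df = records.copy()
    if df["bd_g_cm3"].isna().any():
        raise ValueError("missing bulk density: saturation stocks are undefined")
    depth_m = df["depth_cm"].to_numpy(float) / 100.0
    bd = df["bd_g_cm3"].to_numpy(float)
    slope = df["mineral_type"].map({m: f.slope_gkg_per_pct for m, f in fits.items()}).to_numpy(float)
    mocmax_stock = slope * df["cs_pct"].to_numpy(float) * bd * depth_m * KG_M2_TO_T_HA

    moc_stock = (
        df["moc_initial_stock_t_ha"].to_numpy(float)
        if "moc_initial_stock_t_ha" in df.columns
        else np.full(len(df), np.nan)
    )
    need = ~np.isfinite(moc_stock)
    if need.any():
        if soc_cs_model is None:
            raise ValueError(f"{int(need.sum())} records lack measured MOC and no SOC+CS model given")
        sub = df.loc[need]
        soc_conc = sub["initial_stock_t_ha"].to_numpy(float) / (
            sub["bd_g_cm3"].to_numpy(float) * (sub["depth_cm"].to_numpy(float) / 100.0) * KG_M2_TO_T_HA
        )
        frame = pd.DataFrame({"soc_g_kg": soc_conc, "cs_pct": sub["cs_pct"].to_numpy(float)})
        moc_conc = soc_cs_model.predict_mean(encode_features(frame, soc_cs_model.feature_spec))
        moc_stock[need] = moc_conc * bd[need] * depth_m[need] * KG_M2_TO_T_HA

    df["moc_max_stock_t_ha"] = mocmax_stock
    df["moc_initial_stock_t_ha"] = moc_stock
    df["pct_saturation"] = 100.0 * moc_stock / mocmax_stock
    df["oversaturated_flag"] = df["pct_saturation"] > 100.0
    return df


# ---------------------------------------------------------------------------
# Asymptotic regression
# ---------------------------------------------------------------------------

@dataclass
class AsymptoticFit:
    """rate(s) = asym + (r0 - asym) * exp(-exp(lrc) * s), s a fraction."""

    asym: float
    r0: float
    lrc: float
    tau: str | float
    n: int
    r2: float
    sse: float

    def predict(self, s):
        s = np.asarray(s, dtype=float)
        out = self.asym + (self.r0 - self.asym) * np.exp(-np.exp(self.lrc) * s)
        return float(out) if out.ndim == 0 else out

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def _model(params: np.ndarray, s: np.ndarray) -> np.ndarray:
    asym, r0, lrc = params
    return asym + (r0 - asym) * np.exp(-np.exp(lrc) * s)


def _start_grid(rates: np.ndarray) -> list[np.ndarray]:
    lo, hi = float(np.min(rates)), float(np.max(rates))
    starts = []
    for asym0 in (0.0, lo):
        for lrc0 in (-2.0, -1.0, 0.0, 1.0, 2.0):
            starts.append(np.array([asym0, hi, lrc0]))
    return starts


def fit_asymptotic(
    saturation: Sequence[float],
    rates: Sequence[float],
    tau: str | float = "mean",
    starts: Sequence[Sequence[float]] | None = None,
    seed: int | None = None,
    min_points: int = 10,
) -> AsymptoticFit:
    """Fit the asymptotic accrual model by multi-start optimisation.

    Parameters
    ----------
    saturation
        %C saturation as *fractions* (0.5 for 50%).
    rates
        Accrual rates, t C ha-1 yr-1 (negative values allowed).
    tau
        "mean" for nonlinear least squares; a level in (0,1) for a quantile
        envelope under the pinball loss (the 10th/90th quantile curves).
    starts
        Optional extra start points (asym, r0, lrc) added to the built-in
        deterministic grid.

    R2 is 1 - SSE/SST about the mean, reported for every tau.
    """
    s = np.asarray(saturation, dtype=float)
    r = np.asarray(rates, dtype=float)
    if s.size < min_points:
        raise ValueError(f"need >= {min_points} points, got {s.size}")
    if np.ptp(r) == 0.0:  # constant rates: degenerate flat fit
        return AsymptoticFit(float(r[0]), float(r[0]), 0.0, tau, s.size, 1.0, 0.0)

    start_list = _start_grid(r)
    if starts is not None:
        start_list += [np.asarray(p, float) for p in starts]

    best_params, best_loss = None, np.inf
    if tau == "mean":
        for x0 in start_list:
            try:
                res = optimize.least_squares(lambda p: _model(p, s) - r, x0, method="lm", max_nfev=5000)
            except Exception:
                continue
            loss = float(np.sum(res.fun**2))
            if res.success and loss < best_loss:
                best_loss, best_params = loss, res.x
    else:
        tau_f = float(tau)
        if not 0.0 < tau_f < 1.0:
            raise ValueError(f"tau must be 'mean' or in (0,1), got {tau}")

        def pinball(p):
            e = r - _model(p, s)
            return float(np.sum(np.where(e >= 0, tau_f * e, (tau_f - 1) * e)))

        for x0 in start_list:
            res = optimize.minimize(pinball, x0, method="Nelder-Mead",
                                    options={"maxiter": 4000, "xatol": 1e-9, "fatol": 1e-12})
            if res.fun < best_loss:
                best_loss, best_params = float(res.fun), res.x
    if best_params is None:
        raise RuntimeError(
            f"asymptotic fit did not converge from any of {len(start_list)} starts "
            f"(n={s.size}, rate range [{r.min():.3g}, {r.max():.3g}])"
        )
    resid = r - _model(best_params, s)
    sst = float(np.sum((r - r.mean()) ** 2))
    sse = float(np.sum(resid**2))
    fit = AsymptoticFit(
        asym=float(best_params[0]),
        r0=float(best_params[1]),
        lrc=float(best_params[2]),
        tau=tau,
        n=int(s.size),
        r2=1.0 - sse / sst if sst > 0 else 1.0,
        sse=best_loss if tau != "mean" else sse,
    )
    if fit.asym < 0:
        logger.warning("fitted asymptote is negative (%.3g): losses at high saturation", fit.asym)
    return fit


def accrual_sensitivity(
    records: pd.DataFrame,
    exclusions: Mapping[str, Callable[[pd.DataFrame], pd.Series]],
    tau: str | float = "mean",
) -> pd.DataFrame:
    """Refit the model under named record-exclusion sets.

    ``exclusions`` maps a label to a predicate returning the rows to drop.
    Reports parameter deltas against the full-data fit and whether the
    declining trend (r0 > asym) persists.
    """
    s = records["pct_saturation"].to_numpy(float) / 100.0
    r = records["rate_t_ha_yr"].to_numpy(float)
    base = fit_asymptotic(s, r, tau=tau)
    rows = [
        {
            "exclusion": "none",
            "n": base.n,
            "asym": base.asym,
            "r0": base.r0,
            "lrc": base.lrc,
            "d_asym": 0.0,
            "d_r0": 0.0,
            "d_lrc": 0.0,
            "declining": base.r0 > base.asym,
        }
    ]
    for label, predicate in exclusions.items():
        drop = predicate(records).to_numpy(bool)
        keep = ~drop
        if keep.sum() == 0:
            raise ValueError(f"exclusion {label!r} empties the dataset")
        fit = fit_asymptotic(s[keep], r[keep], tau=tau)
        rows.append(
            {
                "exclusion": label,
                "n": fit.n,
                "asym": fit.asym,
                "r0": fit.r0,
                "lrc": fit.lrc,
                "d_asym": fit.asym - base.asym,
                "d_r0": fit.r0 - base.r0,
                "d_lrc": fit.lrc - base.lrc,
                "declining": fit.r0 > fit.asym,
            }
        )
    return pd.DataFrame(rows)


def potential_accrual_map(
    saturation_layer_pct: xr.DataArray,
    fit: AsymptoticFit,
    stack: GridStack,
) -> tuple[xr.DataArray, float]:
    """Potential accrual rate over croplands and its global total.

    Applies the mean fitted curve to the topsoil %C saturation map on
    unmasked cropland cells; the total is area-weighted, in Pg C yr-1
    (1 t ha-1 yr-1 over A km2 is A x 100 t yr-1).
    """
    mask = _get_mask(stack)
    cropland = stack.layer("cropland").to_numpy().astype(float) > 0.5
    sat = saturation_layer_pct.to_numpy().astype(float) / 100.0
    rate = np.where(~mask & cropland & np.isfinite(sat), fit.predict(sat), np.nan)
    areas_ha = _area_grid_m2(stack) / 1e4
    use = np.isfinite(rate)
    total_pg = float(np.sum(rate[use] * areas_ha[use]) / 1e9)  # t -> Pg
    da = xr.DataArray(rate, coords=saturation_layer_pct.coords, dims=saturation_layer_pct.dims)
    return da, total_pg
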