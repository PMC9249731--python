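"""Ensemble random-forest modelling of mineral-associated carbon (MOC).

An ensemble of independently trained random-forest regressors (default 300
members, 400 trees each, 75-25 train-test split per member) provides:

* attribution — permutation importance on each member's held-out quarter,
  and partial-dependence curves of the ensemble-mean predictor,
  f_hat(x_s) = (1/n) sum_i f(x_s, x_C^(i)),
  averaging the model over the empirical background distribution of the
  remaining covariates (optionally restricted to subsets of a conditioning
  variable, e.g. low/medium/high POC regimes);
* prediction — per-row ensemble means with 90% intervals from the 5th and
  95th percentiles of member predictions;
* validation — spatially buffered leave-one-out CV over a ladder of buffer
  radii, and hold-out (block) CV by soil order or study.

Three feature sets mirror the analysis stages: an attribution set using POC,
a prediction set using SOC (a global POC map does not exist), and a compact
SOC+CS set used to impute MOC for accrual records.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor

from .profiles_io import MINERAL_TYPES, SOIL_ORDERS, VEGETATION_CLASSES

logger = logging.getLogger("mocsat")

TARGET = "moc_g_kg"

FEATURE_SPECS: dict[str, tuple[str, ...]] = {
    "attribution": ("cs_pct", "mat_c", "map_mm", "poc_g_kg", "vegetation", "mineral_type"),
    "prediction": ("cs_pct", "mat_c", "map_mm", "soc_g_kg", "vegetation", "mineral_type"),
    "accrual": ("soc_g_kg", "cs_pct"),
}

#: Fixed category orders for deterministic integer encoding (trees are
#: invariant to any monotone recoding, so integer codes suffice).
_CATEGORY_ORDERS: dict[str, tuple[str, ...]] = {
    "vegetation": VEGETATION_CLASSES,
    "mineral_type": MINERAL_TYPES,
    "soil_order": SOIL_ORDERS,
    "management": ("natural", "managed"),
    "depth_class": ("topsoil", "subsoil"),
}

EARTH_RADIUS_KM = 6371.0


def encode_features(df: pd.DataFrame, features: Sequence[str]) -> np.ndarray:
    """Encode a feature frame as a float matrix with fixed category codes.

    Unseen categorical levels are fatal (a tree model cannot extrapolate to
    a level it never saw)."""
    cols = []
    for name in features:
        if name not in df.columns:
            raise ValueError(f"missing feature column: {name}")
        col = df[name]
        if name in _CATEGORY_ORDERS:
            order = _CATEGORY_ORDERS[name]
            codes = pd.Categorical(col, categories=order).codes.astype(float)
            if (codes < 0).any():
                bad = sorted(set(col[pd.Categorical(col, categories=order).codes < 0]))
                raise ValueError(f"unseen category level(s) in {name}: {bad}")
            cols.append(codes)
        else:
            cols.append(pd.to_numeric(col, errors="raise").to_numpy(float))
    return np.column_stack(cols)


@dataclass
class MemberRecord:
    model: RandomForestRegressor
    train_idx: np.ndarray
    test_idx: np.ndarray
    mae: float
    mse: float
    r2: float


@dataclass
class EnsembleModel:
    """A bag of independently trained RF regressors with split bookkeeping."""

    feature_spec: tuple[str, ...]
    members: list[MemberRecord]
    X: np.ndarray
    y: np.ndarray
    seed: int
    trees_per_member: int
    split_fraction: float

    @property
    def n_members(self) -> int:
        return len(self.members)

    @property
    def mean_r2(self) -> float:
        return float(np.mean([m.r2 for m in self.members]))

    @property
    def sd_r2(self) -> float:
        return float(np.std([m.r2 for m in self.members], ddof=1)) if self.n_members > 1 else 0.0

    def member_predictions(self, X: np.ndarray) -> np.ndarray:
        """(n_members, n_rows) matrix of member predictions."""
        return np.vstack([m.model.predict(X) for m in self.members])

    def predict_mean(self, X: np.ndarray) -> np.ndarray:
        """The ensemble-mean predictor used for PD and mapping."""
        return self.member_predictions(X).mean(axis=0)

    def metrics_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "member": np.arange(self.n_members),
                "mae": [m.mae for m in self.members],
                "mse": [m.mse for m in self.members],
                "r2": [m.r2 for m in self.members],
            }
        )


@dataclass
class PartialDependence:
    variable: str
    grid: np.ndarray
    pd_values: np.ndarray
    condition: str | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variable": self.variable,
                "grid": self.grid,
                "pd": self.pd_values,
                "condition": self.condition or "",
            }
        )


def _complete_cases(records: pd.DataFrame, features: Sequence[str], target: str) -> pd.DataFrame:
    cols = list(features) + [target]
    return records.dropna(subset=[c for c in cols if c in records.columns])


def train_ensemble(
    records: pd.DataFrame,
    feature_spec: str | Sequence[str] = "attribution",
    n_members: int = 300,
    trees: int = 400,
    split_fraction: float = 0.75,
    seed: int = 0,
    target: str = TARGET,
    min_cases: int = 50,
) -> EnsembleModel:
    """Train the RF ensemble on complete cases of the chosen feature set.

    Each member draws its own random 75% training subset; MAE, MSE and R2
    are evaluated only on that member's held-out 25%.  Everything is driven
    by ``seed``: the same seed reproduces splits and metrics bitwise.
    """
    features = FEATURE_SPECS[feature_spec] if isinstance(feature_spec, str) else tuple(feature_spec)
    df = _complete_cases(records, features, target)
    if len(df) < min_cases:
        raise ValueError(f"only {len(df)} complete cases (need >= {min_cases})")
    X = encode_features(df, features)
    y = df[target].to_numpy(float)
    n = len(df)
    n_train = int(round(split_fraction * n))
    ss = np.random.SeedSequence(seed)
    member_seeds = ss.generate_state(2 * n_members)
    members: list[MemberRecord] = []
    for k in range(n_members):
        rng = np.random.default_rng(member_seeds[2 * k])
        perm = rng.permutation(n)
        train_idx, test_idx = perm[:n_train], perm[n_train:]
        model = RandomForestRegressor(
            n_estimators=trees,
            random_state=int(member_seeds[2 * k + 1] % (2**31)),
            n_jobs=1,
        )
        model.fit(X[train_idx], y[train_idx])
        if test_idx.size:
            pred = model.predict(X[test_idx])
            resid = y[test_idx] - pred
            sst = float(np.sum((y[test_idx] - y[test_idx].mean()) ** 2))
            r2 = 1.0 - float(np.sum(resid**2)) / sst if sst > 0 else 0.0
            mae = float(np.mean(np.abs(resid)))
            mse = float(np.mean(resid**2))
        else:
            mae = mse = 0.0
            r2 = 1.0
        members.append(MemberRecord(model, train_idx, test_idx, mae, mse, r2))
    ens = EnsembleModel(
        feature_spec=features,
        members=members,
        X=X,
        y=y,
        seed=seed,
        trees_per_member=trees,
        split_fraction=split_fraction,
    )
    logger.info(
        "trained %d-member ensemble on %d cases: test R2 = %.3f +/- %.3f",
        n_members,
        n,
        ens.mean_r2,
        ens.sd_r2,
    )
    return ens


def predict_with_interval(
    model: EnsembleModel, rows: pd.DataFrame | np.ndarray
) -> pd.DataFrame:
    """Per-row ensemble mean with a 90% interval (5th/95th member quantiles)."""
    X = rows if isinstance(rows, np.ndarray) else encode_features(rows, model.feature_spec)
    preds = model.member_predictions(X)
    return pd.DataFrame(
        {
            "mean": preds.mean(axis=0),
            "q05": np.percentile(preds, 5.0, axis=0),
            "q95": np.percentile(preds, 95.0, axis=0),
        }
    )


def permutation_importance(
    model: EnsembleModel, records: pd.DataFrame | None = None, seed: int = 0
) -> pd.DataFrame:
    """Rank features by mean increase in held-out MSE when permuted.

    For each member, each feature column of that member's test matrix is
    permuted (with a seeded generator) and the member's test MSE recomputed;
    the importance is the average of MSE(permuted) - MSE(original).
    """
    if records is not None:
        X = encode_features(records, model.feature_spec)
        y = pd.to_numeric(records[TARGET]).to_numpy(float)
    else:
        X, y = model.X, model.y
    rng = np.random.default_rng(seed)
    n_feat = X.shape[1]
    deltas = np.zeros(n_feat)
    for member in model.members:
        idx = member.test_idx if records is None else np.arange(len(y))
        Xt, yt = X[idx], y[idx]
        base_mse = float(np.mean((member.model.predict(Xt) - yt) ** 2))
        for j in range(n_feat):
            Xp = Xt.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            deltas[j] += float(np.mean((member.model.predict(Xp) - yt) ** 2)) - base_mse
    deltas /= model.n_members
    out = pd.DataFrame({"feature": list(model.feature_spec), "delta_mse": deltas})
    return out.sort_values("delta_mse", ascending=False).reset_index(drop=True)


def partial_dependence(
    model: EnsembleModel,
    variable: str,
    grid: Sequence[float],
    background: np.ndarray | None = None,
) -> PartialDependence:
    """Marginal effect of one variable on the ensemble-mean prediction.

    For each grid value g the variable's column of the background matrix is
    set to g and predictions are averaged over all background rows.
    """
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")
    X_bg = model.X if background is None else np.asarray(background, float)
    if X_bg.shape[0] == 0:
        raise ValueError("empty background")
    j = list(model.feature_spec).index(variable)
    values = np.empty(grid.size)
    for i, g in enumerate(grid):
        Xg = X_bg.copy()
        Xg[:, j] = g
        values[i] = float(model.predict_mean(Xg).mean())
    return PartialDependence(variable, grid, values)


def conditional_partial_dependence(
    model: EnsembleModel,
    variable: str,
    grid: Sequence[float],
    condition_var: str = "poc_g_kg",
    breakpoints: tuple[float, float] | None = None,
    min_rows: int = 10,
) -> dict[str, PartialDependence]:
    """Partial dependence within low/medium/high regimes of a conditioning
    variable (default POC; breakpoints default to its median and third
    quartile, which track the saturation thresholds of the POC response)."""
    k = list(model.feature_spec).index(condition_var)
    cond = model.X[:, k]
    if breakpoints is None:
        breakpoints = (float(np.median(cond)), float(np.percentile(cond, 75.0)))
    lo, hi = breakpoints
    if lo > hi:
        raise ValueError(f"breakpoints must be ordered, got {breakpoints}")
    regimes = {
        "L": cond <= lo,
        "M": (cond > lo) & (cond <= hi),
        "H": cond > hi,
    }
    if lo == hi:  # constant conditioning variable: the regimes coincide
        regimes = {name: np.ones(cond.size, dtype=bool) for name in regimes}
    out: dict[str, PartialDependence] = {}
    for name, mask in regimes.items():
        if int(mask.sum()) < min_rows:
            raise ValueError(
                f"regime {name} has {int(mask.sum())} background rows (need >= {min_rows})"
            )
        pdep = partial_dependence(model, variable, grid, background=model.X[mask])
        pdep.condition = f"{condition_var}:{name}"
        out[name] = pdep
    return out


def haversine_km(lat1, lon1, lat2, lon2):
    """Great-circle distance in km (sphere of radius 6371 km)."""
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(v, float)) for v in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return EARTH_RADIUS_KM * 2 * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


@dataclass
class BufferedCVResult:
    radii_km: np.ndarray
    r2: np.ndarray
    trend_slope: float
    trend_pvalue: float
    n_test: int
    skipped: int = 0


def buffered_loo_cv(
    records: pd.DataFrame,
    feature_spec: str | Sequence[str] = "prediction",
    radii_km: Sequence[float] = tuple(range(0, 151, 25)),
    seed: int = 0,
    trees: int = 100,
    max_test_points: int = 500,
    target: str = TARGET,
) -> BufferedCVResult:
    """Spatially buffered leave-one-out cross-validation.

    For each buffer radius and each test point, a forest is trained on all
    points strictly farther than the radius (great-circle distance) and the
    held-out point is predicted; R2 is pooled over all LOO predictions at
    that radius.  A linear regression of R2 on radius tests whether
    performance degrades as near-duplicate neighbours are excluded (spatial
    autocorrelation leaking into apparent skill).  Radius 0 is plain
    leave-one-out provided site coordinates are distinct.
    """
    features = FEATURE_SPECS[feature_spec] if isinstance(feature_spec, str) else tuple(feature_spec)
    df = _complete_cases(records, features, target)
    df = df.dropna(subset=["lat", "lon"])
    if len(df) < 20:
        raise ValueError(f"too few located records for buffered CV: {len(df)}")
    X = encode_features(df, features)
    y = df[target].to_numpy(float)
    lat = df["lat"].to_numpy(float)
    lon = df["lon"].to_numpy(float)
    n = len(df)
    rng = np.random.default_rng(seed)
    test_pts = np.sort(rng.choice(n, size=min(n, max_test_points), replace=False))
    dists = haversine_km(lat[test_pts, None], lon[test_pts, None], lat[None, :], lon[None, :])
    radii = np.asarray(list(radii_km), dtype=float)
    r2s = np.empty(radii.size)
    skipped_total = 0
    for ri, radius in enumerate(radii):
        preds, obs = [], []
        for ti, i in enumerate(test_pts):
            train_mask = dists[ti] > radius
            train_mask[i] = False
            if not train_mask.any():
                skipped_total += 1
                logger.warning("radius %.0f km: point %d has no training data, skipped", radius, i)
                continue
            model = RandomForestRegressor(
                n_estimators=trees, random_state=seed + ri * 100003 + ti, n_jobs=1
            )
            model.fit(X[train_mask], y[train_mask])
            preds.append(float(model.predict(X[i : i + 1])[0]))
            obs.append(y[i])
        obs_a, pred_a = np.asarray(obs), np.asarray(preds)
        sst = float(np.sum((obs_a - obs_a.mean()) ** 2))
        r2s[ri] = 1.0 - float(np.sum((obs_a - pred_a) ** 2)) / sst if sst > 0 else 0.0
    if radii.size >= 3:
        fit = stats.linregress(radii, r2s)
        trend_slope, trend_pvalue = float(fit.slope), float(fit.pvalue)
    else:  # a trend needs at least 3 radii
        trend_slope = trend_pvalue = float("nan")
    return BufferedCVResult(
        radii_km=radii,
        r2=r2s,
        trend_slope=trend_slope,
        trend_pvalue=trend_pvalue,
        n_test=test_pts.size,
        skipped=skipped_total,
    )


def holdout_cv_by_group(
    records: pd.DataFrame,
    group_var: str = "soil_order",
    feature_spec: str | Sequence[str] = "prediction",
    seed: int = 0,
    trees: int = 100,
    min_group: int = 10,
    target: str = TARGET,
) -> pd.DataFrame:
    """Hold-out (block) cross-validation by soil order or study.

    Each group in turn is completely withheld, a forest is trained on the
    remainder, and the group's out-of-sample R2 is reported; groups with
    fewer than ``min_group`` records are skipped with a warning.
    """
    features = FEATURE_SPECS[feature_spec] if isinstance(feature_spec, str) else tuple(feature_spec)
    df = _complete_cases(records, features, target)
    groups = df[group_var].dropna().unique()
    if len(groups) < 2:
        raise ValueError(f"need >= 2 groups in {group_var}, got {len(groups)}")
    rows = []
    for gi, g in enumerate(sorted(groups)):
        mask = (df[group_var] == g).to_numpy()
        if int(mask.sum()) < min_group:
            logger.warning("group %s skipped (n=%d < %d)", g, int(mask.sum()), min_group)
            continue
        X = encode_features(df, features)
        y = df[target].to_numpy(float)
        model = RandomForestRegressor(n_estimators=trees, random_state=seed + gi, n_jobs=1)
        model.fit(X[~mask], y[~mask])
        pred = model.predict(X[mask])
        sst = float(np.sum((y[mask] - y[mask].mean()) ** 2))
        r2 = 1.0 - float(np.sum((y[mask] - pred) ** 2)) / sst if sst > 0 else np.nan
        rows.append({"group": g, "n": int(mask.sum()), "r2": r2})
    if len(rows) < 2:
        raise ValueError("fewer than 2 usable groups after skipping small ones")
    return pd.DataFrame(rows)
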