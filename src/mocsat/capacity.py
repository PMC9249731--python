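"""Boundary-line estimation of the mineralogical carbon capacity (MOC_max).

The capacity of a soil to hold mineral-associated organic carbon is modelled
as an upper envelope linear in clay+silt content (CS, %), with a distinct
slope for high-activity (HM) and low-activity (LM) mineral soils:

    MOC_max = slope(mineral type) * CS

The slope is estimated as an upper quantile (default: the 95th) of the
MOC-vs-CS scatter, fitted through the origin — no mineral-associated carbon
can exist without fine minerals present.  The 95th quantile is a
deliberately conservative envelope given the ~80-120% carbon-recovery
uncertainty of size fractionations, so observed saturation can exceed 100%.

For a single covariate with a forced zero intercept the pinball-loss
minimiser has a closed form: the tau-th x-weighted quantile of the ratios
y_i/x_i.  That closed form is used here (and checked against a dense grid
search over the pinball objective in the test suite).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("mocsat")

#: Unit conversion from g C kg-1 soil per %CS to mg C g-1 mineral:
#: 1 %CS is 10 g mineral per kg soil, so a slope of 1 g C kg-1 soil per %
#: equals 0.1 g C = 100 mg C per g mineral.
GKG_PER_PCT_TO_MG_PER_G = 100.0


@dataclass
class BoundaryFit:
    """A fitted per-mineral-type boundary line (quantile slope with CI)."""

    mineral_type: str
    tau: float
    slope_gkg_per_pct: float
    ci_low: float
    ci_high: float
    n_points: int
    n_boot: int
    seed: int | None = None
    quantile_curve: list[tuple[float, float]] | None = None

    @property
    def slope_mg_per_g_mineral(self) -> float:
        return convert_slope_units(self.slope_gkg_per_pct)

    def to_json(self, path: str | Path | None = None) -> str:
        doc = asdict(self)
        doc["slope_mg_per_g_mineral"] = self.slope_mg_per_g_mineral
        text = json.dumps(doc, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, path: str | Path) -> "BoundaryFit":
        doc = json.loads(Path(path).read_text())
        doc.pop("slope_mg_per_g_mineral", None)
        if doc.get("quantile_curve") is not None:
            doc["quantile_curve"] = [tuple(p) for p in doc["quantile_curve"]]
        return cls(**doc)


def quantile_slope_through_origin(
    x: Sequence[float], y: Sequence[float], tau: float
) -> float:
    """Through-origin quantile-regression slope.

    Minimises the pinball loss  sum_i rho_tau(y_i - beta * x_i)  over
    beta >= 0 for strictly positive x.  The minimiser is the tau-th
    x-weighted quantile of the ratios y_i / x_i; at quantile jumps the lower
    ratio is taken (left-continuous convention).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2:
        raise ValueError(f"need at least 2 points, got {x.size}")
    if np.any(x <= 0):
        raise ValueError("all x (clay+silt %) must be > 0 for a through-origin fit")
    if not 0.0 < tau < 1.0:
        raise ValueError(f"tau must be in (0,1), got {tau}")
    ratios = y / x
    order = np.argsort(ratios, kind="stable")
    r_sorted = ratios[order]
    w_sorted = x[order]
    cumw = np.cumsum(w_sorted)
    threshold = tau * cumw[-1]
    idx = int(np.searchsorted(cumw, threshold, side="left"))
    idx = min(idx, r_sorted.size - 1)
    return float(max(r_sorted[idx], 0.0))


def _fit_subset(
    records: pd.DataFrame,
    mineral_type: str,
    natural_only: bool = True,
    cutoffs: Iterable[int] = (63,),
) -> pd.DataFrame:
    """Rows entering a boundary fit: one mineral type, natural ecosystems,
    the clay+silt (not clay-only) fraction cutoffs, MOC and CS present."""
    df = records
    mask = (
        (df["mineral_type"] == mineral_type)
        & df["moc_g_kg"].notna()
        & (df["cs_pct"] > 0)
        & df["fraction_cutoff_um"].isin(list(cutoffs))
    )
    if natural_only:
        mask &= df["management"] == "natural"
    return df.loc[mask]


def boundary_fit(
    records: pd.DataFrame,
    mineral_type: str,
    tau: float = 0.95,
    n_boot: int = 1000,
    seed: int | None = None,
    cutoffs: Iterable[int] = (63,),
    natural_only: bool = True,
    min_points: int = 10,
) -> BoundaryFit:
    """Fit the boundary-line slope for one mineral type with a bootstrap CI.

    The slope is the tau-th quantile slope through the origin on natural-
    ecosystem records of the requested fraction cutoffs.  The 90% confidence
    interval is a percentile bootstrap resampling whole profiles (site_id),
    not individual layers, to respect within-profile dependence.
    """
    sub = _fit_subset(records, mineral_type, natural_only, cutoffs)
    if len(sub) < min_points:
        raise ValueError(
            f"only {len(sub)} usable points for {mineral_type} (need >= {min_points})"
        )
    x = sub["cs_pct"].to_numpy(float)
    y = sub["moc_g_kg"].to_numpy(float)
    slope = quantile_slope_through_origin(x, y, tau)

    if n_boot <= 1:
        lo = hi = slope
    else:
        rng = np.random.default_rng(seed)
        sites = sub["site_id"].to_numpy()
        unique_sites = np.unique(sites)
        groups = {s: np.flatnonzero(sites == s) for s in unique_sites}
        boots = np.empty(n_boot)
        for b in range(n_boot):
            chosen = rng.choice(unique_sites, size=unique_sites.size, replace=True)
            idx = np.concatenate([groups[s] for s in chosen])
            boots[b] = quantile_slope_through_origin(x[idx], y[idx], tau)
        lo, hi = np.percentile(boots, [5.0, 95.0])
    return BoundaryFit(
        mineral_type=mineral_type,
        tau=tau,
        slope_gkg_per_pct=slope,
        ci_low=float(min(lo, slope)),
        ci_high=float(max(hi, slope)),
        n_points=len(sub),
        n_boot=n_boot,
        seed=seed,
    )


def quantile_sensitivity(
    records: pd.DataFrame,
    mineral_type: str,
    taus: Sequence[float],
    cutoffs: Iterable[int] = (63,),
    natural_only: bool = True,
    min_points: int = 10,
) -> list[tuple[float, float]]:
    """Boundary slopes over a ladder of quantile levels (sensitivity check).

    On a fixed dataset the slope is non-decreasing in tau.  Duplicate levels
    are deduplicated with a warning.
    """
    taus = list(taus)
    unique = sorted(set(taus))
    if len(unique) < len(taus):
        logger.warning("duplicate quantile levels removed: %s", taus)
    sub = _fit_subset(records, mineral_type, natural_only, cutoffs)
    if len(sub) < min_points:
        raise ValueError(
            f"only {len(sub)} usable points for {mineral_type} (need >= {min_points})"
        )
    x = sub["cs_pct"].to_numpy(float)
    y = sub["moc_g_kg"].to_numpy(float)
    return [(t, quantile_slope_through_origin(x, y, t)) for t in unique]


def moc_max_of(cs_pct, mineral_type: str, fits: dict[str, BoundaryFit]):
    """MOC_max (g C kg-1 soil) for a given clay+silt content and mineral type.

    Depth-independent by construction: the capacity is an intrinsic property
    of the soil mineralogy.
    """
    cs = np.asarray(cs_pct, dtype=float)
    if np.any((cs <= 0) | (cs > 100)):
        raise ValueError("cs_pct must be in (0,100]")
    slope = fits[mineral_type].slope_gkg_per_pct
    out = slope * cs
    return float(out) if np.isscalar(cs_pct) else out


def convert_slope_units(slope_gkg_per_pct: float) -> float:
    """Convert a boundary slope from g C kg-1 soil per %CS to mg C g-1 mineral."""
    if slope_gkg_per_pct < 0:
        raise ValueError("slope must be non-negative")
    return GKG_PER_PCT_TO_MG_PER_G * slope_gkg_per_pct
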