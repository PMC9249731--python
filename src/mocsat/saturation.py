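"""Percent mineralogical carbon saturation and deficit statistics.

%C saturation is 100 * MOC / MOC_max: the proximity of a soil to its
mineralogical carbon capacity.  Its complement, the deficit MOC_max - MOC,
is the additional carbon the mineral matrix could in principle hold.
Because MOC_max is a conservative 95th-quantile envelope, individual soils
can sit above 100% saturation; such values are retained and flagged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .capacity import BoundaryFit

logger = logging.getLogger("mocsat")

#: Groups with at most this many observations are suppressed from the
#: ecosystem-by-depth summaries.
MIN_GROUP_N = 5


@dataclass
class GroupSummary:
    group: str
    n: int
    mean_pct: float
    ci95_halfwidth: float
    median_pct: float
    q1_pct: float
    q3_pct: float


def percent_saturation(moc_g_kg, moc_max_g_kg):
    """100 * MOC / MOC_max; values above 100% are permitted."""
    moc = np.asarray(moc_g_kg, dtype=float)
    cap = np.asarray(moc_max_g_kg, dtype=float)
    if np.any(cap <= 0):
        raise ValueError("moc_max must be > 0")
    out = 100.0 * moc / cap
    return float(out) if out.ndim == 0 else out


def compute_saturation(
    records: pd.DataFrame, fits: dict[str, BoundaryFit]
) -> pd.DataFrame:
    """Per-record MOC_max, %C saturation and deficit.

    Records quality-flagged for MOC > recovery-tolerance * SOC are excluded
    from these ratio statistics (they remain in the upstream table and in
    boundary fitting).
    """
    df = records
    usable = df["moc_g_kg"].notna() & (df["cs_pct"] > 0)
    if "recovery_flag" in df.columns:
        usable &= ~df["recovery_flag"].fillna(False).astype(bool)
    out = df.loc[usable].copy()
    slopes = out["mineral_type"].map(
        {m: f.slope_gkg_per_pct for m, f in fits.items()}
    )
    out["moc_max_g_kg"] = slopes * out["cs_pct"]
    out["pct_saturation"] = percent_saturation(
        out["moc_g_kg"].to_numpy(), out["moc_max_g_kg"].to_numpy()
    )
    out["deficit_g_kg"] = out["moc_max_g_kg"] - out["moc_g_kg"]
    out["oversaturated_flag"] = out["pct_saturation"] > 100.0
    n_over = int(out["oversaturated_flag"].sum())
    if n_over:
        logger.info("%d records above 100%% C saturation (flagged, retained)", n_over)
    return out


def _summary(label: str, values: np.ndarray) -> GroupSummary:
    n = values.size
    mean = float(np.mean(values))
    if n > 1 and np.std(values) > 0:
        half = float(
            stats.t.ppf(0.975, n - 1) * np.std(values, ddof=1) / np.sqrt(n)
        )
    else:
        half = 0.0
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return GroupSummary(label, n, mean, half, float(med), float(q1), float(q3))


def group_saturation(
    results: pd.DataFrame,
    grouping: str = "management",
    min_n: int = MIN_GROUP_N,
) -> list[GroupSummary]:
    """Grouped %C saturation summaries (means with 95% CI, box statistics).

    ``grouping`` is one of ``management``, ``depth``, or ``ecosystem_depth``
    (ecosystem group crossed with topsoil/subsoil; groups with <= ``min_n``
    observations suppressed).
    """
    if results.empty:
        raise ValueError("no saturation results to group")
    df = results
    if grouping == "management":
        keys = df["management"]
    elif grouping == "depth":
        keys = df["depth_class"]
    elif grouping == "ecosystem_depth":
        keys = df["ecosystem_group"] + ":" + df["depth_class"]
    else:
        raise ValueError(f"unknown grouping: {grouping!r}")
    out: list[GroupSummary] = []
    for label, sub in df.groupby(keys, sort=True):
        if grouping == "ecosystem_depth" and len(sub) <= min_n:
            logger.info("group %s suppressed (n=%d <= %d)", label, len(sub), min_n)
            continue
        out.append(_summary(str(label), sub["pct_saturation"].to_numpy(float)))
    if not out:
        raise ValueError("all groups suppressed or empty")
    return out


def summaries_to_frame(summaries: Sequence[GroupSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "group": s.group,
                "n": s.n,
                "mean": s.mean_pct,
                "ci95": s.ci95_halfwidth,
                "median": s.median_pct,
                "q1": s.q1_pct,
                "q3": s.q3_pct,
            }
            for s in summaries
        ]
    )


def compare_groups(a: Sequence[float], b: Sequence[float]) -> tuple[float, float, float]:
    """Welch two-sample t-test on %C saturation.

    Returns (statistic, degrees of freedom, two-sided p).  Fatal if both
    groups are degenerate (zero variance).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    if va == 0 and vb == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, float(a.size + b.size - 2), 1.0
        raise ValueError("degenerate variance in both groups")
    res = stats.ttest_ind(a, b, equal_var=False)
    df = float(getattr(res, "df", np.nan))
    return float(res.statistic), df, float(res.pvalue)
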