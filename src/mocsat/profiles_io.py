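"""Soil-profile tables: data model, CSV I/O, validation, and categorical rules.

The observational unit is a depth-resolved soil measurement ("profile layer")
with climate covariates, carbon fractions (MOC/POC/SOC), and the categorical
labels (mineral type, management, ecosystem group) that the downstream
boundary-line, saturation, and machine-learning analyses condition on.

Conventions fixed at ingest: temperatures in deg C, precipitation in mm yr-1,
clay+silt (CS) in mass %, carbon concentrations in g C kg-1 soil, bulk
density in g cm-3.  No unit autodetection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("mocsat")

# ---------------------------------------------------------------------------
# Categorical vocabularies
# ---------------------------------------------------------------------------

#: The 11 USDA soil orders of the mineral-soil synthesis (Histosols excluded).
SOIL_ORDERS: tuple[str, ...] = (
    "Alfisol",
    "Andisol",
    "Aridisol",
    "Entisol",
    "Gelisol",
    "Inceptisol",
    "Mollisol",
    "Oxisol",
    "Spodosol",
    "Ultisol",
    "Vertisol",
)

VEGETATION_CLASSES: tuple[str, ...] = (
    "boreal_forest",
    "temperate_forest",
    "tropical_forest",
    "grassland",
    "savanna",
    "shrubland",
    "cropland",
    "other",
)

MINERAL_TYPES: tuple[str, ...] = ("HM", "LM")
DEPTH_CLASSES: tuple[str, ...] = ("topsoil", "subsoil")
MANAGEMENT_CLASSES: tuple[str, ...] = ("natural", "managed")
FRACTION_CUTOFFS_UM: tuple[int, ...] = (2, 20, 63)

#: Order-based mineral-activity default: low-activity (1:1, kaolinitic) soils
#: are LM at all depths; most 2:1-clay orders are HM at all depths; young /
#: amorphous-mineral orders switch activity class with depth.
_LM_ALL_DEPTHS = frozenset({"Oxisol", "Ultisol"})
_HM_ALL_DEPTHS = frozenset(
    {"Alfisol", "Aridisol", "Gelisol", "Inceptisol", "Mollisol", "Spodosol", "Vertisol"}
)
_DEPTH_DEPENDENT = frozenset({"Andisol", "Entisol"})

#: Keywords in free-text clay-composition statements that override the
#: order-based default.  2:1 clays -> HM, 1:1 clays -> LM.
_HM_CLAY_KEYWORDS = ("2:1", "illite", "smectite", "vermiculite", "chlorite", "montmorillonite")
_LM_CLAY_KEYWORDS = ("1:1", "kaolinite", "kaolinitic", "gibbsite")

#: Broad ecosystem groups used for managed-vs-natural comparisons; savannas
#: are grouped with grasslands.
ECOSYSTEM_GROUPS: Mapping[str, str] = {
    "boreal_forest": "forest",
    "temperate_forest": "forest",
    "tropical_forest": "forest",
    "grassland": "grassland",
    "savanna": "grassland",
    "shrubland": "shrubland",
    "cropland": "cropland",
    "other": "other",
}

# Columns required in an input table (post column-map renaming).
REQUIRED_COLUMNS: tuple[str, ...] = (
    "site_id",
    "study_id",
    "depth_top_cm",
    "depth_bottom_cm",
    "cs_pct",
    "soil_order",
    "vegetation",
    "fraction_cutoff_um",
)

NUMERIC_COLUMNS: tuple[str, ...] = (
    "lat",
    "lon",
    "depth_top_cm",
    "depth_bottom_cm",
    "mat_c",
    "map_mm",
    "cs_pct",
    "moc_g_kg",
    "poc_g_kg",
    "soc_g_kg",
    "bd_g_cm3",
    "fraction_cutoff_um",
)

ALL_COLUMNS: tuple[str, ...] = (
    "site_id",
    "study_id",
    "lat",
    "lon",
    "depth_top_cm",
    "depth_bottom_cm",
    "depth_class",
    "mat_c",
    "map_mm",
    "cs_pct",
    "soil_order",
    "mineral_type",
    "vegetation",
    "management",
    "ecosystem_group",
    "moc_g_kg",
    "poc_g_kg",
    "soc_g_kg",
    "bd_g_cm3",
    "fraction_cutoff_um",
    "recovery_flag",
)

#: MOC may exceed SOC by up to this factor before a record is quality-flagged
#: (size-fractionation C recovery ranged roughly 80-120% across studies).
RECOVERY_TOLERANCE = 1.25

#: CS synthesis range; values below are flagged, not rejected.
CS_SYNTHESIS_MIN = 1.5


class ProfileValidationError(ValueError):
    """Fatal problem with a profile table (missing columns, empty file...)."""


# ---------------------------------------------------------------------------
# Classification rules
# ---------------------------------------------------------------------------

def classify_mineral_type(
    soil_order: str, depth_class: str, clay_info: str | None = None
) -> str:
    """Assign high- (HM) or low-activity (LM) mineral type.

    An explicit clay-composition statement (dominant 2:1 vs 1:1 clays)
    overrides the order-based default.  Defaults: Oxisols and Ultisols are LM
    at all depths; Alfisols, Aridisols, Gelisols, Inceptisols, Mollisols,
    Spodosols and Vertisols are HM; Andisols and Entisols are HM in topsoil
    (0-30 cm) and LM in subsoil (30-100 cm).
    """
    if soil_order not in SOIL_ORDERS:
        raise ValueError(f"unknown soil order: {soil_order!r}")
    if depth_class not in DEPTH_CLASSES:
        raise ValueError(f"unknown depth class: {depth_class!r}")
    if clay_info:
        text = clay_info.lower()
        if any(k in text for k in _LM_CLAY_KEYWORDS):
            return "LM"
        if any(k in text for k in _HM_CLAY_KEYWORDS):
            return "HM"
    if soil_order in _LM_ALL_DEPTHS:
        return "LM"
    if soil_order in _HM_ALL_DEPTHS:
        return "HM"
    assert soil_order in _DEPTH_DEPENDENT
    return "HM" if depth_class == "topsoil" else "LM"


def assign_management(vegetation: str) -> tuple[str, str]:
    """Map a land-cover class to (management, ecosystem_group).

    Croplands are managed; forests, grasslands (incl. savannas) and
    shrublands are natural/less-managed.
    """
    if vegetation not in VEGETATION_CLASSES:
        raise ValueError(f"unknown vegetation class: {vegetation!r}")
    management = "managed" if vegetation == "cropland" else "natural"
    return management, ECOSYSTEM_GROUPS[vegetation]


def depth_class_of(depth_top_cm: float, depth_bottom_cm: float) -> str:
    """Topsoil/subsoil split at 30 cm using the interval midpoint."""
    midpoint = 0.5 * (depth_top_cm + depth_bottom_cm)
    return "topsoil" if midpoint < 30.0 else "subsoil"


# ---------------------------------------------------------------------------
# Reading / validation
# ---------------------------------------------------------------------------

@dataclass
class DatasetSummary:
    """Bookkeeping counts for a validated profile table."""

    n_profiles: int
    n_layers: int
    n_moc: int
    n_poc: int
    n_soc: int
    by_management: dict[str, int] = field(default_factory=dict)
    by_vegetation: dict[str, int] = field(default_factory=dict)
    by_mineral_type: dict[str, int] = field(default_factory=dict)
    by_depth_class: dict[str, int] = field(default_factory=dict)


def _coerce_numeric(df: pd.DataFrame) -> pd.DataFrame:
    for col in NUMERIC_COLUMNS:
        if col in df.columns:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna() & (df[col].astype(str).str.strip() != "")
            if bad.any():
                logger.warning(
                    "column %s: %d unparsable numeric cells set to null", col, int(bad.sum())
                )
            df[col] = coerced
    return df


def read_profiles(
    path: str | Path, column_map: Mapping[str, str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read and validate a profile CSV.

    Parameters
    ----------
    path
        CSV file with a header row (RFC 4180, UTF-8).
    column_map
        Optional mapping from source header names to canonical column names.

    Returns
    -------
    (accepted, rejected)
        ``accepted`` carries the canonical columns plus derived labels
        (depth_class, mineral_type, management, ecosystem_group,
        recovery_flag); ``rejected`` has the original rows plus a ``reason``
        column.  Unparsable numeric cells become nulls with a logged warning;
        whole-row failures are rejections, never silent drops.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if df.empty:
        raise ProfileValidationError(f"empty profile table: {path}")
    if column_map:
        df = df.rename(columns=dict(column_map))
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ProfileValidationError(f"missing required columns: {missing}")
    for col in ALL_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan if col in NUMERIC_COLUMNS else pd.Series(np.nan, index=df.index, dtype=object)
    if df["mineral_type"].dtype != object:
        df["mineral_type"] = df["mineral_type"].astype(object)
    df = _coerce_numeric(df)

    reasons = pd.Series("", index=df.index, dtype=object)

    def _mark(mask: pd.Series, reason: str) -> None:
        fresh = mask & (reasons == "")
        reasons[fresh] = reason

    _mark(df["soil_order"].isin(["Histosol"]), "organic soil excluded")
    _mark(~df["soil_order"].isin(SOIL_ORDERS), "unknown soil order")
    _mark(~df["vegetation"].isin(VEGETATION_CLASSES), "unknown vegetation class")
    _mark(
        ~(df["cs_pct"] > 0) | (df["cs_pct"] > 100),
        "cs_pct out of (0,100]",
    )
    _mark(df["depth_top_cm"].isna() | (df["depth_top_cm"] < 0), "invalid depth_top_cm")
    _mark(
        df["depth_bottom_cm"].isna() | (df["depth_bottom_cm"] <= df["depth_top_cm"]),
        "depth_bottom_cm must exceed depth_top_cm",
    )
    _mark(
        ~df["fraction_cutoff_um"].isin(FRACTION_CUTOFFS_UM),
        "fraction_cutoff_um not in {2, 20, 63}",
    )
    for col in ("moc_g_kg", "poc_g_kg", "soc_g_kg"):
        _mark(df[col] < 0, f"negative {col}")
    _mark(df["bd_g_cm3"] <= 0, "non-positive bd_g_cm3")
    _mark(df["lat"].abs() > 90, "lat out of [-90,90]")
    _mark(df["lon"].abs() > 180, "lon out of [-180,180]")

    rejected = df[reasons != ""].copy()
    rejected["reason"] = reasons[reasons != ""]
    accepted = df[reasons == ""].copy()

    if not accepted.empty:
        accepted["depth_class"] = [
            depth_class_of(t, b)
            for t, b in zip(accepted["depth_top_cm"], accepted["depth_bottom_cm"])
        ]
        need_mineral = accepted["mineral_type"].isna() | ~accepted["mineral_type"].isin(
            MINERAL_TYPES
        )
        accepted.loc[need_mineral, "mineral_type"] = [
            classify_mineral_type(o, d)
            for o, d in zip(
                accepted.loc[need_mineral, "soil_order"],
                accepted.loc[need_mineral, "depth_class"],
            )
        ]
        mgmt = [assign_management(v) for v in accepted["vegetation"]]
        accepted["management"] = [m for m, _ in mgmt]
        accepted["ecosystem_group"] = [g for _, g in mgmt]
        # MOC exceeding SOC beyond fractionation-recovery tolerance: keep the
        # record but flag it; flagged records are excluded from ratio
        # statistics downstream, not from boundary fitting.
        both = accepted["moc_g_kg"].notna() & accepted["soc_g_kg"].notna()
        accepted["recovery_flag"] = both & (
            accepted["moc_g_kg"] > RECOVERY_TOLERANCE * accepted["soc_g_kg"]
        )
        low_cs = accepted["cs_pct"] < CS_SYNTHESIS_MIN
        if low_cs.any():
            logger.warning(
                "%d records below the %.1f%% CS synthesis range (kept, flagged)",
                int(low_cs.sum()),
                CS_SYNTHESIS_MIN,
            )
        accepted["cs_range_flag"] = low_cs
    logger.info(
        "read %d rows from %s: %d accepted, %d rejected",
        len(df),
        path.name,
        len(accepted),
        len(rejected),
    )
    return accepted.reset_index(drop=True), rejected.reset_index(drop=True)


def write_profiles(df: pd.DataFrame, path: str | Path) -> None:
    """Write a validated profile table back to CSV (round-trip safe)."""
    cols = [c for c in ALL_COLUMNS if c in df.columns]
    extra = [c for c in df.columns if c not in cols]
    df[cols + extra].to_csv(path, index=False)


def write_rejections(rejected: pd.DataFrame, path: str | Path) -> None:
    rejected.to_csv(path, index=False)


def summarize_dataset(df: pd.DataFrame) -> DatasetSummary:
    """Synthesis bookkeeping: layer/profile counts by measurement and category."""
    if df.empty:
        return DatasetSummary(0, 0, 0, 0, 0)

    def _counts(col: str) -> dict[str, int]:
        if col not in df.columns:
            return {}
        return {str(k): int(v) for k, v in df[col].value_counts(dropna=True).items()}

    return DatasetSummary(
        n_profiles=int(df["site_id"].nunique()),
        n_layers=len(df),
        n_moc=int(df["moc_g_kg"].notna().sum()) if "moc_g_kg" in df.columns else 0,
        n_poc=int(df["poc_g_kg"].notna().sum()) if "poc_g_kg" in df.columns else 0,
        n_soc=int(df["soc_g_kg"].notna().sum()) if "soc_g_kg" in df.columns else 0,
        by_management=_counts("management"),
        by_vegetation=_counts("vegetation"),
        by_mineral_type=_counts("mineral_type"),
        by_depth_class=_counts("depth_class"),
    )
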