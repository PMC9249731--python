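"""Gridded upscaling: capacity and carbon-stock maps on a lat-lon grid.

A :class:`GridStack` is a set of co-registered 0.5-degree (configurable)
raster layers — clay+silt, bulk density, SOC, climate, land cover, mineral
type, organic-soil fraction — for two depth intervals, topsoil (0-30 cm)
and subsoil (30-100 cm).  From it the module derives MOC_max maps (boundary
slope x CS), predicted-MOC maps, areal stocks (kg C m-2), global totals in
Pg C, %C saturation and deficit maps, and the deficit relative to an
environmental limit set by the natural-land average saturation.

Mineral-soil masking: cells with >50% organic soils (Histosols + Gelisols)
are excluded, as are tundra, desert, barren and ice land covers (the class
list is configuration, not hard-coded).  Masked cells contribute to no
aggregate.

Raster I/O is NetCDF (CF-style lat/lon coordinates, float32 layers, NaN as
nodata), read and written through xarray.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import xarray as xr

from .capacity import BoundaryFit
from .profiles_io import MINERAL_TYPES, VEGETATION_CLASSES
from .rf_model import EnsembleModel, encode_features

logger = logging.getLogger("mocsat")

#: Depth-interval thicknesses (m) used for stock integration.
DEPTH_THICKNESS_M: dict[str, float] = {"topsoil": 0.30, "subsoil": 0.70}
DEPTHS: tuple[str, ...] = ("topsoil", "subsoil")

#: Default land-cover code table (code = index).  A coarser or finer source
#: classification (e.g. a 16-class satellite product) is collapsed onto this
#: table via a config-supplied lookup before building a stack.
LANDCOVER_CLASSES: tuple[str, ...] = (
    "water",
    "boreal_forest",
    "temperate_forest",
    "tropical_forest",
    "grassland",
    "savanna",
    "shrubland",
    "cropland",
    "tundra",
    "desert",
    "barren",
    "ice",
)

#: Land covers excluded from all mineral-soil aggregates.
DEFAULT_MASK_CLASSES: tuple[str, ...] = ("water", "tundra", "desert", "barren", "ice")

#: Organic-soil (Histosol + Gelisol) areal fraction above which a cell is
#: excluded; strictly greater-than.
ORGANIC_FRACTION_MAX = 50.0

#: Natural-land average %C saturation per depth (fractions), the default
#: environmental limit on attainable MOC.
DEFAULT_S_NAT: dict[str, float] = {"topsoil": 0.51, "subsoil": 0.19}

EARTH_RADIUS_KM = 6371.0

#: Land-cover class -> vegetation class of the profile synthesis, for
#: building RF feature frames from grid layers.
_LANDCOVER_TO_VEGETATION: dict[str, str] = {
    "boreal_forest": "boreal_forest",
    "temperate_forest": "temperate_forest",
    "tropical_forest": "tropical_forest",
    "grassland": "grassland",
    "savanna": "savanna",
    "shrubland": "shrubland",
    "cropland": "cropland",
}


class GridError(ValueError):
    """Fatal grid problem (missing layer, mis-registered layers...)."""


@dataclass
class StockSummary:
    quantity: str
    depth: str
    total_pg: float
    range_pg: tuple[float, float] | None = None
    n_cells: int = 0


class GridStack:
    """Co-registered raster layers plus a mineral-soil mask.

    Depth-resolved layers are stored as ``{name}_{depth}`` variables
    (e.g. ``cs_pct_topsoil``); depth-independent layers (``mat_c``,
    ``map_mm``, ``organic_fraction``, ``land_cover``, ``cropland``) by bare
    name.  All variables must share the (lat, lon) coordinates; this is
    enforced at construction and load.
    """

    def __init__(self, ds: xr.Dataset, resolution_deg: float | None = None):
        if "lat" not in ds.coords or "lon" not in ds.coords:
            raise GridError("GridStack requires lat and lon coordinates")
        for name, var in ds.data_vars.items():
            if tuple(var.dims) != ("lat", "lon"):
                raise GridError(f"layer {name} has dims {var.dims}, expected (lat, lon)")
        self.ds = ds
        if resolution_deg is None:
            resolution_deg = float(ds.attrs.get("resolution_deg", 0.5))
        self.resolution_deg = resolution_deg
        self.ds.attrs["resolution_deg"] = resolution_deg

    # -- layer access -----------------------------------------------------
    def layer(self, name: str, depth: str | None = None) -> xr.DataArray:
        key = f"{name}_{depth}" if depth else name
        if key not in self.ds:
            raise GridError(f"missing layer: {key}")
        return self.ds[key]

    def has_layer(self, name: str, depth: str | None = None) -> bool:
        key = f"{name}_{depth}" if depth else name
        return key in self.ds

    def set_layer(self, name: str, data, depth: str | None = None) -> None:
        key = f"{name}_{depth}" if depth else name
        arr = np.asarray(data, dtype=np.float32)
        if arr.shape != (self.ds.sizes["lat"], self.ds.sizes["lon"]):
            raise GridError(f"layer {key} shape {arr.shape} does not match grid")
        self.ds[key] = (("lat", "lon"), arr)

    @property
    def lat(self) -> np.ndarray:
        return self.ds["lat"].to_numpy()

    @property
    def lon(self) -> np.ndarray:
        return self.ds["lon"].to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.ds.sizes["lat"], self.ds.sizes["lon"]

    # -- I/O ---------------------------------------------------------------
    def to_netcdf(self, path: str | Path) -> None:
        ds = self.ds.copy()
        for name in ds.data_vars:
            ds[name] = ds[name].astype(np.float32)
        ds.to_netcdf(path, engine="scipy")

    @classmethod
    def open_netcdf(cls, path: str | Path) -> "GridStack":
        ds = xr.open_dataset(path, engine="scipy").load()
        return cls(ds)


def build_mask(
    stack: GridStack,
    mask_classes: Iterable[str] = DEFAULT_MASK_CLASSES,
    landcover_classes: Sequence[str] = LANDCOVER_CLASSES,
) -> xr.DataArray:
    """Boolean exclusion mask (True = cell excluded from every aggregate).

    A cell is masked when its organic-soil fraction exceeds 50% (strict) or
    its land cover falls in ``mask_classes``.  The mask is stored on the
    stack as the ``mask`` layer and applied uniformly downstream.
    """
    for required in ("organic_fraction", "land_cover"):
        if not stack.has_layer(required):
            raise GridError(f"missing layer: {required}")
    organic = stack.layer("organic_fraction")
    lc = stack.layer("land_cover").to_numpy()
    codes = {landcover_classes.index(c) for c in mask_classes if c in landcover_classes}
    lc_masked = np.isin(lc, list(codes)) | ~np.isfinite(lc)
    mask = (organic.to_numpy() > ORGANIC_FRACTION_MAX) | ~np.isfinite(organic.to_numpy()) | lc_masked
    da = xr.DataArray(mask, coords={"lat": stack.lat, "lon": stack.lon}, dims=("lat", "lon"))
    stack.ds["mask"] = da.astype(np.float32)  # float for NetCDF3 round-trips
    logger.info("mask excludes %d of %d cells", int(mask.sum()), mask.size)
    return da


def _get_mask(stack: GridStack) -> np.ndarray:
    if stack.has_layer("mask"):
        return stack.layer("mask").to_numpy() > 0.5
    return build_mask(stack).to_numpy()


def moc_max_map(
    stack: GridStack, fits: Mapping[str, BoundaryFit], depth: str
) -> xr.DataArray:
    """Per-cell mineralogical capacity (g C kg-1): slope(mineral type) x CS."""
    cs = stack.layer("cs_pct", depth).to_numpy().astype(float)
    mineral = stack.layer("mineral_type", depth).to_numpy().astype(float)
    mask = _get_mask(stack)
    slopes = np.full_like(cs, np.nan)
    for code, mt in enumerate(MINERAL_TYPES):
        slopes[mineral == code] = fits[mt].slope_gkg_per_pct
    out = slopes * cs
    out[mask] = np.nan
    n_null = int(np.sum(~mask & ~np.isfinite(out)))
    if n_null:
        logger.warning("moc_max_map: %d unmasked cells null (missing CS or mineral)", n_null)
    return xr.DataArray(out, coords={"lat": stack.lat, "lon": stack.lon}, dims=("lat", "lon"))


def stock_kg_m2(conc_g_kg, bd_g_cm3, depth_m: float):
    """Areal stock: concentration (g C kg-1) x bulk density (g cm-3) x depth (m).

    The unit product collapses to kg C m-2 exactly (1 g cm-3 = 1000 kg m-3).
    """
    bd = np.asarray(bd_g_cm3, dtype=float)
    if np.any(bd[np.isfinite(bd)] <= 0):
        raise ValueError("bulk density must be positive")
    out = np.asarray(conc_g_kg, dtype=float) * bd * depth_m
    return float(out) if out.ndim == 0 else out


def cell_area_km2(lat_center, resolution_deg: float):
    """Area of a lat-lon cell by the exact spherical band formula.

    R^2 * dlambda * (sin(phi2) - sin(phi1)) with R = 6371 km.
    """
    lat = np.asarray(lat_center, dtype=float)
    half = resolution_deg / 2.0
    phi1 = np.radians(lat - half)
    phi2 = np.radians(lat + half)
    dlam = np.radians(resolution_deg)
    out = EARTH_RADIUS_KM**2 * dlam * (np.sin(phi2) - np.sin(phi1))
    return float(out) if out.ndim == 0 else out


def _area_grid_m2(stack: GridStack) -> np.ndarray:
    areas = cell_area_km2(stack.lat, stack.resolution_deg) * 1e6  # km2 -> m2
    return np.repeat(areas[:, None], stack.shape[1], axis=1)


def aggregate_stocks(
    stock_layer: xr.DataArray,
    stack: GridStack,
    quantity: str = "stock",
    depth: str = "topsoil",
    range_layers: tuple[xr.DataArray, xr.DataArray] | None = None,
) -> StockSummary:
    """Sum an areal-stock layer (kg C m-2) over unmasked cells, in Pg C.

    1 Pg = 1e12 kg.  Null and masked cells contribute nothing; the total is
    invariant to traversal order and additive over domain splits.
    """
    mask = _get_mask(stack)
    areas = _area_grid_m2(stack)
    vals = stock_layer.to_numpy().astype(float)
    use = ~mask & np.isfinite(vals)

    def _total(v: np.ndarray) -> float:
        return float(np.sum(v[use] * areas[use]) / 1e12)

    rng = None
    if range_layers is not None:
        rng = (
            float(np.nansum(np.where(use, range_layers[0].to_numpy().astype(float) * areas, 0.0)) / 1e12),
            float(np.nansum(np.where(use, range_layers[1].to_numpy().astype(float) * areas, 0.0)) / 1e12),
        )
    return StockSummary(
        quantity=quantity,
        depth=depth,
        total_pg=_total(vals),
        range_pg=rng,
        n_cells=int(use.sum()),
    )


def saturation_and_deficit_maps(
    moc_layer: xr.DataArray, moc_max_layer: xr.DataArray
) -> tuple[xr.DataArray, xr.DataArray]:
    """Per-cell %C saturation (100 x MOC/MOC_max) and deficit (MOC_max - MOC).

    Layers must be co-registered and in the same units (concentrations or
    stocks).  Non-positive capacity on an unmasked cell yields null with a
    warning; nulls propagate.
    """
    if moc_layer.shape != moc_max_layer.shape:
        raise GridError("layers are not co-registered")
    moc = moc_layer.to_numpy().astype(float)
    cap = moc_max_layer.to_numpy().astype(float)
    bad = np.isfinite(cap) & (cap <= 0)
    if bad.any():
        logger.warning("%d cells with non-positive MOC_max set to null", int(bad.sum()))
    cap = np.where(bad, np.nan, cap)
    sat = 100.0 * moc / cap
    deficit = cap - moc
    coords = moc_layer.coords
    return (
        xr.DataArray(sat, coords=coords, dims=moc_layer.dims),
        xr.DataArray(deficit, coords=coords, dims=moc_layer.dims),
    )


def environmental_limit_deficit(
    moc_layer: xr.DataArray,
    moc_max_layer: xr.DataArray,
    depth: str,
    s_nat: Mapping[str, float] = DEFAULT_S_NAT,
) -> xr.DataArray:
    """Deficit relative to the environmental limit s_nat x MOC_max.

    The limit is the natural-land average %C saturation at each depth
    (defaults 51% topsoil, 19% subsoil); soils already above it have zero
    deficit (clamped).
    """
    s = float(s_nat[depth])
    if not 0.0 < s <= 1.0:
        raise ValueError(f"s_nat must be in (0,1], got {s}")
    deficit = s * moc_max_layer.to_numpy().astype(float) - moc_layer.to_numpy().astype(float)
    out = np.maximum(deficit, 0.0)
    return xr.DataArray(out, coords=moc_layer.coords, dims=moc_layer.dims)


def moc_soc_fraction_map(
    moc_layer: xr.DataArray, soc_layer: xr.DataArray
) -> tuple[xr.DataArray, float, float]:
    """MOC/SOC ratio per cell, with its mean and s.d. over finite cells."""
    soc = soc_layer.to_numpy().astype(float)
    soc = np.where(soc > 0, soc, np.nan)
    frac = moc_layer.to_numpy().astype(float) / soc
    finite = np.isfinite(frac)
    mean = float(np.mean(frac[finite])) if finite.any() else np.nan
    sd = float(np.std(frac[finite], ddof=1)) if finite.sum() > 1 else np.nan
    return (
        xr.DataArray(frac, coords=moc_layer.coords, dims=moc_layer.dims),
        mean,
        sd,
    )


def blend_soc(soc_a: xr.DataArray, soc_b: xr.DataArray) -> xr.DataArray:
    """Cellwise mean of two SOC layers (a conservative blended product)."""
    if soc_a.shape != soc_b.shape:
        raise GridError("SOC layers are not co-registered")
    return (soc_a + soc_b) / 2.0


def grid_feature_frame(stack: GridStack, depth: str) -> tuple[pd.DataFrame, np.ndarray]:
    """Tabulate unmasked, complete cells as an RF prediction-feature frame.

    Returns (frame, flat cell indices); land-cover codes are translated to
    the vegetation classes of the profile synthesis, mineral codes to HM/LM.
    """
    mask = _get_mask(stack)
    cs = stack.layer("cs_pct", depth).to_numpy().astype(float)
    soc = stack.layer("soc_g_kg", depth).to_numpy().astype(float)
    mineral = stack.layer("mineral_type", depth).to_numpy().astype(float)
    mat = stack.layer("mat_c").to_numpy().astype(float)
    mapp = stack.layer("map_mm").to_numpy().astype(float)
    lc = stack.layer("land_cover").to_numpy().astype(float)
    veg_names = np.full(lc.shape, "", dtype=object)
    for code, name in enumerate(LANDCOVER_CLASSES):
        veg_names[lc == code] = _LANDCOVER_TO_VEGETATION.get(name, "other")
    ok = (
        ~mask
        & np.isfinite(cs)
        & np.isfinite(soc)
        & np.isfinite(mineral)
        & np.isfinite(mat)
        & np.isfinite(mapp)
        & (veg_names != "")
    )
    idx = np.flatnonzero(ok.ravel())
    frame = pd.DataFrame(
        {
            "cs_pct": cs.ravel()[idx],
            "mat_c": mat.ravel()[idx],
            "map_mm": mapp.ravel()[idx],
            "soc_g_kg": soc.ravel()[idx],
            "vegetation": veg_names.ravel()[idx],
            "mineral_type": np.asarray(MINERAL_TYPES)[
                mineral.ravel()[idx].astype(int)
            ],
        }
    )
    return frame, idx


def predict_moc_map(
    stack: GridStack, model: EnsembleModel, depth: str
) -> dict[str, xr.DataArray]:
    """Predicted MOC concentration map with 90% ensemble intervals.

    Applies the prediction-spec ensemble to every unmasked, complete cell;
    returns ``mean``, ``q05`` and ``q95`` layers (g C kg-1).
    """
    frame, idx = grid_feature_frame(stack, depth)
    if frame.empty:
        raise GridError("no predictable cells")
    X = encode_features(frame, model.feature_spec)
    preds = model.member_predictions(X)
    out: dict[str, xr.DataArray] = {}
    for key, vals in (
        ("mean", preds.mean(axis=0)),
        ("q05", np.percentile(preds, 5.0, axis=0)),
        ("q95", np.percentile(preds, 95.0, axis=0)),
    ):
        flat = np.full(stack.shape[0] * stack.shape[1], np.nan)
        flat[idx] = vals
        out[key] = xr.DataArray(
            flat.reshape(stack.shape),
            coords={"lat": stack.lat, "lon": stack.lon},
            dims=("lat", "lon"),
        )
    return out
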