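"""Common grid definition, cell geometry, masks and NetCDF I/O.

Every pipeline stage works on a single rectilinear latitude/longitude grid
(WGS-84 angular coordinates, north-up: row 0 is the northernmost band, cell
centres at ``lat = lat_max - (i + 0.5) * res``).  Cell areas are computed on
an authalic sphere so that zonal and global sums are exact, and all area
quantities are carried in hectares.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import xarray as xr

#: authalic (equal-area) Earth radius in metres
EARTH_RADIUS_M = 6_371_007.2

#: integer code for ocean / undefined cells in admin masks
NO_DATA = -1

#: fill value used for float layers in NetCDF files
FILL_VALUE = -9999.0

#: square metres per hectare
M2_PER_HA = 10_000.0

#: the CAM percentile levels carried by a cropland-agreement stack
CAM_LEVELS = (2.5, 5.0, 10.0, 25.0, 50.0, 95.0)


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a rectilinear lat/lon grid with square cells."""

    resolution: float = 0.05
    lon_min: float = -180.0
    lon_max: float = 180.0
    lat_min: float = -90.0
    lat_max: float = 90.0

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        for span, name in ((self.lon_max - self.lon_min, "longitude"),
                           (self.lat_max - self.lat_min, "latitude")):
            n = span / self.resolution
            if abs(n - round(n)) > 1e-9 * max(1.0, abs(n)) or round(n) < 1:
                raise ValueError(
                    f"{name} span {span} is not an exact positive multiple "
                    f"of resolution {self.resolution}")

    @property
    def n_rows(self) -> int:
        return round((self.lat_max - self.lat_min) / self.resolution)

    @property
    def n_cols(self) -> int:
        return round((self.lon_max - self.lon_min) / self.resolution)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def lat_centers(self) -> np.ndarray:
        """Cell-centre latitudes, descending (north-up row order)."""
        i = np.arange(self.n_rows)
        return self.lat_max - (i + 0.5) * self.resolution

    def lon_centers(self) -> np.ndarray:
        j = np.arange(self.n_cols)
        return self.lon_min + (j + 0.5) * self.resolution

    def lat_edges(self) -> np.ndarray:
        """Latitude band edges, descending from lat_max to lat_min."""
        return self.lat_max - np.arange(self.n_rows + 1) * self.resolution

    def lon_edges(self) -> np.ndarray:
        return self.lon_min + np.arange(self.n_cols + 1) * self.resolution

    def refine(self, factor: int) -> "GridSpec":
        """Same bounds at ``factor`` times finer resolution."""
        if factor < 1 or int(factor) != factor:
            raise ValueError("refinement factor must be a positive integer")
        return GridSpec(self.resolution / factor, self.lon_min, self.lon_max,
                        self.lat_min, self.lat_max)

    def coarsen(self, factor: int) -> "GridSpec":
        """Same bounds at ``factor`` times coarser resolution."""
        if self.n_rows % factor or self.n_cols % factor:
            raise ValueError("grid shape not divisible by coarsening factor")
        return GridSpec(self.resolution * factor, self.lon_min, self.lon_max,
                        self.lat_min, self.lat_max)


def cell_area(spec: GridSpec, radius: float = EARTH_RADIUS_M) -> np.ndarray:
    """Grid-cell area GA in hectares, constant within each latitude band.

    The area of a spherical quadrangle between meridians dλ apart and
    parallels φ_b..φ_t is ``R² dλ (sin φ_t − sin φ_b)``.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    edges = np.deg2rad(spec.lat_edges())
    dlam = np.deg2rad(spec.resolution)
    band = radius ** 2 * dlam * (np.sin(edges[:-1]) - np.sin(edges[1:]))
    ga_row = band / M2_PER_HA
    return np.broadcast_to(ga_row[:, None], spec.shape).copy()


def compute_LA(GA: np.ndarray, exclusion_fraction: np.ndarray) -> np.ndarray:
    """Land available for cropping: GA minus the excluded land-cover share.

    ``exclusion_fraction`` is the per-cell fraction occupied by water,
    wetland, urban, snow/ice and barren classes.
    """
    excl = np.asarray(exclusion_fraction, dtype=float)
    if np.any((excl < 0) | (excl > 1)):
        raise ValueError("exclusion fraction must lie in [0, 1]")
    return GA * (1.0 - excl)


def exclusion_from_classes(class_raster: np.ndarray,
                           excluded_classes: set[int]) -> np.ndarray:
    """Map a categorical land-cover raster to a 0/1 exclusion fraction."""
    return np.isin(class_raster, sorted(excluded_classes)).astype(float)


def zonal_sum(values: np.ndarray, mask: np.ndarray) -> pd.Series:
    """Exact per-unit totals of ``values`` over the integer-coded ``mask``.

    No-data cells (code < 0) and NaN cells are excluded; units with no
    cells are absent from the result.
    """
    values = np.asarray(values, dtype=float)
    mask = np.asarray(mask)
    if values.shape != mask.shape:
        raise ValueError("value map and mask have different shapes")
    keep = (mask >= 0) & np.isfinite(values)
    codes = mask[keep].ravel()
    vals = values[keep].ravel()
    if codes.size == 0:
        return pd.Series(dtype=float)
    sums = np.bincount(codes, weights=vals)
    present = np.bincount(codes) > 0
    idx = np.nonzero(present)[0]
    return pd.Series(sums[idx], index=idx)


@dataclass
class CellGeometry:
    """Per-cell area (GA) and land available for cropping (LA), hectares."""

    GA: np.ndarray
    LA: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.LA < -1e-9) or np.any(self.LA - self.GA > 1e-6):
            raise ValueError("LA must satisfy 0 <= LA <= GA cell-wise")


@dataclass
class AdminMasks:
    """Level-0 (country) and level-1 (subnational) integer-coded masks."""

    country: np.ndarray
    subnational: np.ndarray
    country_names: dict[int, str] = field(default_factory=dict)
    subnational_names: dict[int, str] = field(default_factory=dict)
    #: subnational code -> parent country code
    parents: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        sub = self.subnational
        cty = self.country
        if sub.shape != cty.shape:
            raise ValueError("country and subnational masks differ in shape")
        for code in np.unique(sub[sub >= 0]):
            owners = np.unique(cty[sub == code])
            if owners.size != 1 or owners[0] < 0:
                raise ValueError(
                    f"subnational unit {code} does not nest in one country")
            self.parents.setdefault(int(code), int(owners[0]))

    def country_codes(self) -> list[int]:
        return [int(c) for c in np.unique(self.country[self.country >= 0])]

    def units_of(self, country_code: int) -> list[int]:
        return sorted(c for c, p in self.parents.items() if p == country_code)


@dataclass
class CamStack:
    """Cropland-agreement percentile maps: cropland area (ha) per cell.

    Maps are cell-wise non-decreasing in percentile level; the 95th level is
    the most inclusive cropland surface and also caps physical crop area.
    """

    maps: dict[float, np.ndarray]

    def __post_init__(self) -> None:
        missing = set(CAM_LEVELS) - set(self.maps)
        if missing:
            raise ValueError(f"CAM stack missing percentile levels {missing}")
        prev = None
        for lev in CAM_LEVELS:
            m = self.maps[lev]
            if np.any(m < 0):
                raise ValueError("CAM maps must be non-negative")
            if prev is not None and np.any(m - prev < -1e-9):
                raise ValueError("CAM maps must be non-decreasing in level")
            prev = m

    def __getitem__(self, level: float) -> np.ndarray:
        return self.maps[level]

    @property
    def cam95(self) -> np.ndarray:
        return self.maps[95.0]

    def presence(self, level: float = 95.0) -> np.ndarray:
        """Binary cropland mask at a percentile level (cells with area > 0)."""
        return self.maps[level] > 0

    def check_against(self, GA: np.ndarray) -> None:
        for lev, m in self.maps.items():
            if np.any(m - GA > 1e-6):
                raise ValueError(f"CAM {lev}th map exceeds cell area")


@dataclass
class CropAreaGrid:
    """Harvested (HA) and physical (CA) area layers for one crop, hectares."""

    crop: str
    HA: np.ndarray
    CA: np.ndarray

    def copy(self) -> "CropAreaGrid":
        return CropAreaGrid(self.crop, self.HA.copy(), self.CA.copy())

    def national_totals(self, country_mask: np.ndarray) -> pd.Series:
        return zonal_sum(self.HA, country_mask)


# ---------------------------------------------------------------------------
# NetCDF I/O
# ---------------------------------------------------------------------------

def _coords(spec: GridSpec) -> dict:
    return {
        "lat": ("lat", spec.lat_centers(),
                {"units": "degrees_north", "long_name": "latitude"}),
        "lon": ("lon", spec.lon_centers(),
                {"units": "degrees_east", "long_name": "longitude"}),
    }


def write_crop_netcdf(path: str | Path, crop: str, HA: np.ndarray,
                      CA: np.ndarray, qual: np.ndarray, set_map: np.ndarray,
                      spec: GridSpec) -> None:
    """Write one crop's harvested/physical area, quality and provenance
    layers (variables ``harvarea``, ``croparea``, ``qual``, ``set``).

    NaN cells in the float layers are stored as the declared fill value and
    restored as NaN on read; ``set`` is an integer layer with NO_DATA fill.
    """
    for layer in (HA, CA, qual, set_map):
        if np.asarray(layer).shape != spec.shape:
            raise ValueError("layer shape does not match grid spec")
    ds = xr.Dataset(
        {
            "harvarea": (("lat", "lon"), np.asarray(HA, dtype=np.float64),
                         {"units": "hectares", "long_name": "Harvested area"}),
            "croparea": (("lat", "lon"), np.asarray(CA, dtype=np.float64),
                         {"units": "hectares",
                          "long_name": "Crop (physical) area"}),
            "qual": (("lat", "lon"), np.asarray(qual, dtype=np.float64),
                     {"long_name": "Data quality"}),
            "set": (("lat", "lon"), np.asarray(set_map, dtype=np.int32),
                    {"long_name": "Best-fit dataset used"}),
        },
        coords=_coords(spec),
        attrs={"crop": crop, "resolution_deg": spec.resolution},
    )
    enc = {v: {"_FillValue": FILL_VALUE} for v in ("harvarea", "croparea",
                                                   "qual")}
    enc["set"] = {"_FillValue": np.int32(NO_DATA)}
    ds.to_netcdf(path, engine="scipy", encoding=enc)


def read_crop_netcdf(path: str | Path) -> dict:
    """Read a per-crop file written by :func:`write_crop_netcdf`."""
    with xr.open_dataset(path, engine="scipy") as ds:
        ds.load()
        missing = {"harvarea", "croparea", "qual", "set"} - set(ds.data_vars)
        if missing:
            raise ValueError(f"crop NetCDF missing variables {missing}")
        set_map = ds["set"].values
        set_map = np.where(np.isnan(set_map), NO_DATA, set_map).astype(np.int32)
        return {
            "crop": ds.attrs.get("crop"),
            "HA": ds["harvarea"].values.astype(np.float64),
            "CA": ds["croparea"].values.astype(np.float64),
            "qual": ds["qual"].values.astype(np.float64),
            "set": set_map,
            "lat": ds["lat"].values,
            "lon": ds["lon"].values,
        }


def write_mask_netcdf(path: str | Path, name: str, mask: np.ndarray,
                      spec: GridSpec,
                      names: Mapping[int, str] | None = None) -> None:
    """Write an integer-coded admin mask (e.g. variable ``country``)."""
    ds = xr.Dataset(
        {name: (("lat", "lon"), np.asarray(mask, dtype=np.int32),
                {"long_name": f"{name} code"})},
        coords=_coords(spec))
    if names:
        ds[name].attrs["codes"] = ";".join(
            f"{k}={v}" for k, v in sorted(names.items()))
    ds.to_netcdf(path, engine="scipy",
                 encoding={name: {"_FillValue": np.int32(NO_DATA)}})


def read_mask_netcdf(path: str | Path, name: str) -> tuple[np.ndarray, dict]:
    with xr.open_dataset(path, engine="scipy") as ds:
        ds.load()
        arr = ds[name].values
        arr = np.where(np.isnan(arr), NO_DATA, arr).astype(np.int32)
        names = {}
        codes = ds[name].attrs.get("codes", "")
        if codes:
            for item in codes.split(";"):
                k, v = item.split("=", 1)
                names[int(k)] = v
        return arr, names
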