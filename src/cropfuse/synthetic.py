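"""Self-contained synthetic worlds with retained ground truth.

A generated world carries everything the pipeline consumes — admin masks,
cell geometry, a cropland-agreement percentile stack, per-crop truth layers,
a national (FAOSTAT-style) reference table, subnational (NSO-style) tables
and a suite of degraded input datasets in all four variable conventions —
so that every stage can be exercised against known truth without downloads.

The default world is a 40 x 80-cell window of the real 0.05-degree grid
(40-42 N, 0-4 E, cell area ~2300 ha) with three countries of two
subnational units each, three crops (two temporary, one permanent), truth
cropping intensity in [1, 1.5] and total crop cover capped at half the
available land, leaving slack for the national adjustment stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .grid import (GridSpec, CellGeometry, AdminMasks, CamStack,
                   CropAreaGrid, NO_DATA, cell_area, compute_LA, zonal_sum)
from .harmonize import (RawLayer, CropClassRegistry, apply_lower_bound,
                        LOWER_BOUND_HA)
from .quality import DatasetMeta

#: percentile multiplier applied to truth total CA for each CAM level
_CAM_MULT = {2.5: 0.6, 5.0: 0.7, 10.0: 0.8, 25.0: 0.9, 50.0: 1.0, 95.0: 1.3}
#: quantile of positive cropland below which a cell drops out of a level
_CAM_CUT = {2.5: 0.35, 5.0: 0.25, 10.0: 0.15, 25.0: 0.05, 50.0: 0.0,
            95.0: 0.0}

DEFAULT_CROPS = {"wheat": "temporary", "maize": "temporary",
                 "oilpalm": "permanent"}


@dataclass
class WorldConfig:
    seed: int = 0
    grid: GridSpec = field(default_factory=lambda: GridSpec(
        resolution=0.05, lon_min=0.0, lon_max=4.0,
        lat_min=40.0, lat_max=42.0))
    n_countries: int = 3
    subunits_per_country: int = 2
    crops: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_CROPS))
    ci_range: tuple[float, float] = (1.0, 1.5)
    cover_cap: float = 0.5       # max fraction of LA under crops
    ocean_margin: int = 2        # no-data frame width, cells
    max_exclusion: float = 0.4   # land-cover exclusion fraction on land

    def __post_init__(self) -> None:
        lo, hi = self.ci_range
        if not (1.0 <= lo <= hi <= 3.0):
            raise ValueError("CI range must lie within [1, 3]")
        interior_cols = self.grid.n_cols - 2 * self.ocean_margin
        interior_rows = self.grid.n_rows - 2 * self.ocean_margin
        if interior_cols < self.n_countries:
            raise ValueError("more countries than interior columns")
        if interior_rows < self.subunits_per_country:
            raise ValueError("more subunits than interior rows")


@dataclass
class DatasetRecord:
    """One synthetic input dataset: metadata, raw per-crop layers and the
    country codes it covers."""

    meta: DatasetMeta
    layers: dict[str, RawLayer]
    countries: list[int]

    @property
    def acronym(self) -> str:
        return self.meta.acronym


@dataclass
class TruthWorld:
    config: WorldConfig
    spec: GridSpec
    geometry: CellGeometry
    masks: AdminMasks
    cam: CamStack
    truth: dict[str, CropAreaGrid]
    crop_registry: CropClassRegistry
    fao_table: pd.DataFrame
    nso_tables: dict[int, pd.DataFrame]
    datasets: list[DatasetRecord]

    def truth_total_CA(self) -> np.ndarray:
        return np.sum([g.CA for g in self.truth.values()], axis=0)


def _smooth_field(rng: np.random.Generator, shape, sigma=2.0) -> np.ndarray:
    f = gaussian_filter(rng.random(shape), sigma=sigma, mode="nearest")
    f -= f.min()
    if f.max() > 0:
        f /= f.max()
    return f


def _build_masks(cfg: WorldConfig) -> AdminMasks:
    nr, nc = cfg.grid.shape
    m = cfg.ocean_margin
    country = np.full((nr, nc), NO_DATA, dtype=np.int32)
    sub = np.full((nr, nc), NO_DATA, dtype=np.int32)
    cols = np.array_split(np.arange(m, nc - m), cfg.n_countries)
    rows = np.array_split(np.arange(m, nr - m), cfg.subunits_per_country)
    cnames, snames = {}, {}
    for ci, cc in enumerate(cols, start=1):
        country[m:nr - m, cc[0]:cc[-1] + 1] = ci
        cnames[ci] = f"country_{ci}"
        for si, rr in enumerate(rows, start=1):
            code = ci * 100 + si
            sub[rr[0]:rr[-1] + 1, cc[0]:cc[-1] + 1] = code
            snames[code] = f"country_{ci}_unit_{si}"
    return AdminMasks(country, sub, cnames, snames)


def _build_cam(total_CA: np.ndarray) -> CamStack:
    pos = total_CA[total_CA > 0]
    maps = {}
    for lev, mult in _CAM_MULT.items():
        m = mult * total_CA
        cut = _CAM_CUT[lev]
        if cut > 0 and pos.size:
            thresh = np.quantile(pos, cut)
            m = np.where(total_CA >= thresh, m, 0.0)
        maps[lev] = m
    return CamStack(maps)


def gen_world(config: WorldConfig | None = None,
              with_datasets: bool = True) -> TruthWorld:
    """Generate a reproducible synthetic world satisfying every input
    consistency rule, with its reference tables derived exactly from truth."""
    cfg = config or WorldConfig()
    rng = np.random.default_rng(cfg.seed)
    spec = cfg.grid
    masks = _build_masks(cfg)
    land = masks.country >= 0

    GA = cell_area(spec)
    exclusion = np.where(land, cfg.max_exclusion *
                         _smooth_field(rng, spec.shape), 1.0)
    LA = compute_LA(GA, exclusion)
    geometry = CellGeometry(GA=GA, LA=LA)

    # truth crop cover: smooth positive fields, thinned to create
    # crop-free cells, jointly capped at cover_cap * LA
    raw_fracs = {}
    for crop in sorted(cfg.crops):
        f = _smooth_field(rng, spec.shape)
        f = np.where(f > np.quantile(f, 0.3), f, 0.0)
        raw_fracs[crop] = np.where(land, f, 0.0)
    total = np.sum(list(raw_fracs.values()), axis=0)
    peak = total.max() if total.max() > 0 else 1.0
    scale = cfg.cover_cap / peak

    truth: dict[str, CropAreaGrid] = {}
    lo, hi = cfg.ci_range
    for crop in sorted(cfg.crops):
        CA = raw_fracs[crop] * scale * LA
        CI = lo + (hi - lo) * _smooth_field(rng, spec.shape)
        HA = CA * CI
        CA, HA = apply_lower_bound(CA, HA)
        truth[crop] = CropAreaGrid(crop, HA, CA)

    cam = _build_cam(np.sum([g.CA for g in truth.values()], axis=0))
    cam.check_against(GA)

    registry = CropClassRegistry(dict(cfg.crops))
    fao = make_national_table(truth, masks)
    nso = {c: gen_nso_table_from(truth, masks, c)
           for c in masks.country_codes()}

    world = TruthWorld(cfg, spec, geometry, masks, cam, truth, registry,
                       fao, nso, [])
    if with_datasets:
        world.datasets = default_dataset_suite(world, rng)
    return world


def make_national_table(truth: dict[str, CropAreaGrid], masks: AdminMasks,
                        year: int = 2020,
                        perturbation: float = 0.0) -> pd.DataFrame:
    """FAOSTAT-style national reference table: exact zonal sums of truth
    harvested area, optionally perturbed by a relative factor."""
    rows = []
    for crop, g in sorted(truth.items()):
        totals = zonal_sum(g.HA, masks.country)
        for code, val in totals.items():
            rows.append({"country": int(code), "crop": crop,
                         "harvested_area_ha": val * (1.0 + perturbation),
                         "year": year})
    return pd.DataFrame(rows)


def gen_nso_table_from(truth: dict[str, CropAreaGrid], masks: AdminMasks,
                       country: int, perturbation: float = 0.0,
                       year: int = 2020) -> pd.DataFrame:
    """NSO-style subnational table for one country, from truth zonal sums."""
    if country not in masks.country_codes():
        raise ValueError(f"unknown country code {country}")
    rows = []
    for crop, g in sorted(truth.items()):
        totals = zonal_sum(g.HA, masks.subnational)
        for code, val in totals.items():
            if masks.parents.get(int(code)) != country:
                continue
            rows.append({"country": country, "unit": int(code), "crop": crop,
                         "harvested_area_ha": val * (1.0 + perturbation),
                         "year": year, "source": f"NSO_{country}"})
    return pd.DataFrame(rows)


def gen_nso_table(world: TruthWorld, country: int,
                  perturbation: float = 0.0) -> pd.DataFrame:
    return gen_nso_table_from(world.truth, world.masks, country,
                              perturbation)


# ---------------------------------------------------------------------------
# Dataset degradation
# ---------------------------------------------------------------------------

def _coarsen_sum(layer: np.ndarray, factor: int) -> np.ndarray:
    nr, nc = layer.shape
    if nr % factor or nc % factor:
        raise ValueError("layer shape not divisible by coarsening factor")
    return layer.reshape(nr // factor, factor, nc // factor,
                         factor).sum(axis=(1, 3))


def _binary_refine(f: np.ndarray, k: int) -> np.ndarray:
    """Deterministic presence pattern on a k-times finer subgrid whose
    block means quantize the requested fractions to multiples of 1/k^2."""
    nr, nc = f.shape
    counts = np.rint(np.clip(f, 0, 1) * k * k).astype(int)
    order = np.arange(k * k).reshape(k, k)
    w = (order[None, :, None, :] < counts[:, None, :, None]).astype(np.int8)
    return w.reshape(nr * k, nc * k)


def degrade_to_dataset(world: TruthWorld, kind: str,
                       resolution_factor: int = 1, *,
                       meta: DatasetMeta, countries: list[int] | None = None,
                       crops: list[str] | None = None,
                       noise_sigma: float = 0.0, flip_prob: float = 0.0,
                       rng: np.random.Generator | None = None,
                       with_ci: bool = False) -> DatasetRecord:
    """Derive a degraded input dataset from truth.

    ``kind`` selects the variable convention (ha, ha_ca, ca, f, w);
    ``resolution_factor`` coarsens area layers (>1) or refines binary
    layers (>1 means a factor-times finer subgrid); ``noise_sigma`` applies
    multiplicative lognormal noise to area content and ``flip_prob``
    Bernoulli flips to binary pixels.
    """
    rng = rng or np.random.default_rng(0)
    countries = countries or world.masks.country_codes()
    crops = crops or sorted(world.truth)
    covered = np.isin(world.masks.country, countries)
    spec = world.spec
    GA = world.geometry.GA

    layers: dict[str, RawLayer] = {}
    for crop in crops:
        g = world.truth[crop]
        HA = np.where(covered, g.HA, 0.0)
        CA = np.where(covered, g.CA, 0.0)
        if noise_sigma > 0:
            factor = rng.lognormal(mean=0.0, sigma=noise_sigma,
                                   size=spec.shape)
            HA = HA * factor
            CA = CA * factor  # same factor keeps CI intact
        if kind in ("ha", "ha_ca", "ca") and resolution_factor > 1:
            src = spec.coarsen(resolution_factor)
            HA = _coarsen_sum(HA, resolution_factor)
            CA = _coarsen_sum(CA, resolution_factor)
        else:
            src = spec

        if kind == "ha":
            layers[crop] = RawLayer(crop, "ha", src, values=HA)
        elif kind == "ha_ca":
            layers[crop] = RawLayer(crop, "ha_ca", src, values=HA,
                                    values2=CA)
        elif kind == "ca":
            ci = None
            if with_ci:
                with np.errstate(invalid="ignore", divide="ignore"):
                    ci = np.where(CA > 0, np.minimum(HA / CA, 3.0), 1.0)
            layers[crop] = RawLayer(crop, "ca", src, values=CA, ci=ci)
        elif kind == "f":
            f = np.clip(CA / GA, 0.0, 1.0)
            layers[crop] = RawLayer(crop, "f", spec, values=f)
        elif kind == "w":
            f = np.clip(CA / GA, 0.0, 1.0)
            w = _binary_refine(f, resolution_factor)
            if flip_prob > 0:
                flips = rng.random(w.shape) < flip_prob
                w = np.where(flips, 1 - w, w)
            layers[crop] = RawLayer(crop, "w",
                                    spec.refine(resolution_factor), values=w)
        else:
            raise ValueError(f"unknown variable kind {kind!r}")
    return DatasetRecord(meta=meta, layers=layers, countries=list(countries))


def default_dataset_suite(world: TruthWorld,
                          rng: np.random.Generator) -> list[DatasetRecord]:
    """The standard study conditions: one coarse legacy dataset covering
    everything, one noise-free high-quality dataset and two noisy rivals
    covering a subset of countries, leaving one country legacy-only."""
    codes = world.masks.country_codes()
    most = codes[:-1] if len(codes) > 1 else codes
    legacy_meta = DatasetMeta(
        "LEGACY", legacy=True,
        overrides={"Qy": 0, "Qa": 0.5, "Qs": 0.5, "Qv": 0.5, "Qr": 0,
                   "Qm": 0, "Qd": 0.5})
    gold_meta = DatasetMeta(
        "GOLD", overrides={"Qy": 0.933, "Qa": 1, "Qs": 0.8, "Qv": 1,
                           "Qr": 0.998, "Qm": 1, "Qd": 1})
    noisyf_meta = DatasetMeta(
        "NOISYF", overrides={"Qy": 0.667, "Qa": 0.5, "Qs": 0.7, "Qv": 0.5,
                             "Qr": 0, "Qm": 0.5, "Qd": 0.5})
    noisyw_meta = DatasetMeta(
        "NOISYW", overrides={"Qy": 0.867, "Qa": 0.5, "Qs": 0.5, "Qv": 0.5,
                             "Qr": 0.4, "Qm": 0, "Qd": 0.5})
    return [
        degrade_to_dataset(world, "ha", resolution_factor=2,
                           meta=legacy_meta, countries=codes, rng=rng),
        degrade_to_dataset(world, "ha_ca", meta=gold_meta, countries=most,
                           rng=rng),
        degrade_to_dataset(world, "f", meta=noisyf_meta, countries=most,
                           noise_sigma=0.2, rng=rng),
        degrade_to_dataset(world, "w", resolution_factor=4, meta=noisyw_meta,
                           countries=most[:1], flip_prob=0.05, rng=rng),
    ]
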