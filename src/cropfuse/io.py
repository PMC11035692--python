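"""Fixture serialization: write a world to NetCDF/CSV files the pipeline
stages can read back, so every stage can also run from a directory of
standard-format inputs rather than an in-memory world."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
import yaml

from .grid import (GridSpec, CellGeometry, AdminMasks, CamStack,
                   CropAreaGrid, CAM_LEVELS, NO_DATA)
from .harmonize import CropClassRegistry, RawLayer
from .quality import DatasetMeta, INDICATOR_NAMES
from .synthetic import DatasetRecord, TruthWorld, WorldConfig


def _lev_name(lev: float) -> str:
    return "cam_" + str(lev).replace(".", "p")


def write_world(outdir: str | Path, world: TruthWorld) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    spec = world.spec
    coords = {"lat": spec.lat_centers(), "lon": spec.lon_centers()}
    data = {
        "country": (("lat", "lon"), world.masks.country.astype(np.int32)),
        "subnational": (("lat", "lon"),
                        world.masks.subnational.astype(np.int32)),
        "LA": (("lat", "lon"), world.geometry.LA),
        "GA": (("lat", "lon"), world.geometry.GA),
    }
    for lev in CAM_LEVELS:
        data[_lev_name(lev)] = (("lat", "lon"), world.cam[lev])
    for crop, g in world.truth.items():
        data[f"truth_HA_{crop}"] = (("lat", "lon"), g.HA)
        data[f"truth_CA_{crop}"] = (("lat", "lon"), g.CA)
    xr.Dataset(data, coords=coords).to_netcdf(out / "world.nc",
                                              engine="scipy")

    world.fao_table.to_csv(out / "fao.csv", index=False)
    for code, df in world.nso_tables.items():
        df.to_csv(out / f"nso_{code}.csv", index=False)
    pd.DataFrame(
        [{"canonical_crop": c, "crop_class": k, "source_name": c}
         for c, k in sorted(world.crop_registry.classes.items())]
    ).to_csv(out / "crop_classes.csv", index=False)

    dsdir = out / "datasets"
    dsdir.mkdir(exist_ok=True)
    meta_rows = []
    for rec in world.datasets:
        m = rec.meta
        row = {"acronym": m.acronym, "legacy": int(m.legacy),
               "countries": ";".join(map(str, rec.countries))}
        row.update({n: m.overrides.get(n) for n in INDICATOR_NAMES})
        meta_rows.append(row)
        for crop, raw in rec.layers.items():
            vars_ = {"values": (("lat", "lon"),
                                np.asarray(raw.values, dtype=float))}
            if raw.values2 is not None:
                vars_["values2"] = (("lat", "lon"),
                                    np.asarray(raw.values2, dtype=float))
            if raw.ci is not None:
                vars_["ci"] = (("lat", "lon"),
                               np.asarray(raw.ci, dtype=float))
            ds = xr.Dataset(
                vars_,
                coords={"lat": raw.spec.lat_centers(),
                        "lon": raw.spec.lon_centers()},
                attrs={"kind": raw.kind, "crop": crop,
                       "resolution": raw.spec.resolution,
                       "lon_min": raw.spec.lon_min,
                       "lon_max": raw.spec.lon_max,
                       "lat_min": raw.spec.lat_min,
                       "lat_max": raw.spec.lat_max})
            ds.to_netcdf(dsdir / f"{m.acronym}__{crop}.nc", engine="scipy")
    pd.DataFrame(meta_rows).to_csv(out / "datasets.csv", index=False)

    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump({
            "seed": world.config.seed,
            "resolution": spec.resolution,
            "lon_min": spec.lon_min, "lon_max": spec.lon_max,
            "lat_min": spec.lat_min, "lat_max": spec.lat_max,
        }, fh)


def load_world(indir: str | Path) -> TruthWorld:
    ind = Path(indir)
    with open(ind / "config.yaml") as fh:
        cfg = yaml.safe_load(fh)
    spec = GridSpec(cfg["resolution"], cfg["lon_min"], cfg["lon_max"],
                    cfg["lat_min"], cfg["lat_max"])
    with xr.open_dataset(ind / "world.nc", engine="scipy") as ds:
        ds.load()
        country = ds["country"].values.astype(np.int32)
        sub = ds["subnational"].values.astype(np.int32)
        geometry = CellGeometry(GA=ds["GA"].values.astype(float),
                                LA=ds["LA"].values.astype(float))
        cam = CamStack({lev: ds[_lev_name(lev)].values.astype(float)
                        for lev in CAM_LEVELS})
        truth = {}
        for name in ds.data_vars:
            if name.startswith("truth_HA_"):
                crop = name[len("truth_HA_"):]
                truth[crop] = CropAreaGrid(
                    crop, ds[name].values.astype(float),
                    ds[f"truth_CA_{crop}"].values.astype(float))
    masks = AdminMasks(country, sub)
    registry = CropClassRegistry.from_csv(ind / "crop_classes.csv")
    fao = pd.read_csv(ind / "fao.csv")
    nso = {}
    for p in sorted(ind.glob("nso_*.csv")):
        code = int(p.stem.split("_", 1)[1])
        nso[code] = pd.read_csv(p)

    datasets = []
    meta_df = pd.read_csv(ind / "datasets.csv")
    for _, row in meta_df.iterrows():
        overrides = {n: float(row[n]) for n in INDICATOR_NAMES
                     if pd.notna(row[n])}
        meta = DatasetMeta(row["acronym"], legacy=bool(int(row["legacy"])),
                           overrides=overrides)
        countries = [int(c) for c in str(row["countries"]).split(";")]
        layers = {}
        for p in sorted((ind / "datasets").glob(f"{meta.acronym}__*.nc")):
            with xr.open_dataset(p, engine="scipy") as lds:
                lds.load()
                lspec = GridSpec(lds.attrs["resolution"],
                                 lds.attrs["lon_min"], lds.attrs["lon_max"],
                                 lds.attrs["lat_min"], lds.attrs["lat_max"])
                kind = lds.attrs["kind"]
                vals = lds["values"].values
                vals = vals.astype(np.int8 if kind == "w" else float)
                layers[lds.attrs["crop"]] = RawLayer(
                    lds.attrs["crop"], kind, lspec, values=vals,
                    values2=(lds["values2"].values.astype(float)
                             if "values2" in lds else None),
                    ci=(lds["ci"].values.astype(float)
                        if "ci" in lds else None))
        datasets.append(DatasetRecord(meta=meta, layers=layers,
                                      countries=countries))

    config = WorldConfig(seed=int(cfg["seed"]), grid=spec,
                         n_countries=len(masks.country_codes()))
    return TruthWorld(config, spec, geometry, masks, cam, truth, registry,
                      fao, nso, datasets)
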