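"""End-to-end orchestration of the six construction stages.

Given a world (synthetic or loaded from fixture files), the pipeline
harmonizes every input dataset, scores datasets per (crop, country),
selects and mosaics the winners, gap-fills legacy-only pairs from
subnational statistics, adjusts national totals to the reference table and
computes the validation statistics.  Every stage is a pure, deterministic
function of its inputs, so stage-wise runs recompose bitwise into the full
pipeline result.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import adjust as adjust_mod
from .assemble import (Candidate, CandidateSet, SelectionMosaic,
                       SelectionResult, build_mosaic, select_best)
from .gapfill import gapfill_pair, gapfill_quality
from .grid import CropAreaGrid, zonal_sum
from .harmonize import consistency_check, harmonize_layer
from .metrics import cam_coverage, temporary_permanent_split, validation_report
from .quality import EndogenousScores, endogenous_scores, q_cam, q_fao
from .synthetic import TruthWorld
from .uncertainty import uncertainty_report

#: endogenous scores attributed to subnational statistical offices when
#: painting the quality layer of gap-filled cells (tabular official data:
#: current, national, survey-based, government dispatch, no grid)
NSO_ENDO = EndogenousScores(Qy=1, Qa=1, Qs=0.5, Qv=0, Qr=0, Qm=1, Qd=1)

#: provenance code painted on cells gap-filled from subnational statistics
NSO_CODE = 99


@dataclass
class PipelineResult:
    world: TruthWorld
    harmonized: dict[str, dict[str, CropAreaGrid]]
    scores: pd.DataFrame
    candidate_sets: dict[tuple[str, int], CandidateSet]
    selections: list[SelectionResult]
    mosaic: SelectionMosaic
    gapfill_reports: dict[tuple[str, int], dict] = field(default_factory=dict)
    adjust_reports: list = field(default_factory=list)
    validation: pd.DataFrame | None = None
    cam_report: object = None
    class_split: pd.DataFrame | None = None
    uncertainty: pd.DataFrame | None = None

    def dataset_codes(self) -> dict[str, int]:
        return {rec.acronym: i + 1
                for i, rec in enumerate(self.world.datasets)}

    def national_table(self) -> pd.DataFrame:
        """Final national harvested-area totals per (crop, country)."""
        rows = []
        for crop, grid in sorted(self.mosaic.crops.items()):
            for code, val in zonal_sum(grid.HA,
                                       self.world.masks.country).items():
                rows.append({"crop": crop, "country": int(code),
                             "harvested_area_ha": float(val)})
        return pd.DataFrame(rows)


def harmonize_all(world: TruthWorld) -> dict[str, dict[str, CropAreaGrid]]:
    """Stage 1: every dataset's raw layers to (HA, CA) on the common grid,
    verified against the consistency diagnostics."""
    out: dict[str, dict[str, CropAreaGrid]] = {}
    for rec in world.datasets:
        crops = {}
        for crop, raw in rec.layers.items():
            g = harmonize_layer(raw, world.spec, world.geometry, world.cam,
                                world.crop_registry)
            rep = consistency_check(g, world.geometry.LA, world.geometry.GA)
            if not rep.ok:
                raise RuntimeError(
                    f"harmonization of {rec.acronym}/{crop} violates "
                    f"consistency rules: {sorted(rep.violations)}")
            crops[g.crop] = g
        out[rec.acronym] = crops
    return out


def _fao_lookup(fao_table: pd.DataFrame) -> dict[tuple[str, int], float]:
    return {(row["crop"], int(row["country"])): float(row["harvested_area_ha"])
            for _, row in fao_table.iterrows()}


def score_all(world: TruthWorld,
              harmonized: dict[str, dict[str, CropAreaGrid]]) -> pd.DataFrame:
    """Stages 2-3: endogenous scores per dataset and exogenous scores per
    (dataset, crop, country)."""
    fao = _fao_lookup(world.fao_table)
    cam_presence = world.cam.presence(95.0)
    rows = []
    for rec in world.datasets:
        endo = endogenous_scores(rec.meta)
        for crop, grid in sorted(harmonized[rec.acronym].items()):
            for country in rec.countries:
                ha_total = float(
                    grid.HA[world.masks.country == country].sum())
                qc = q_cam(grid.CA, cam_presence, world.masks.country,
                           country)
                qf = q_fao(ha_total, fao.get((crop, country)))
                row = {"dataset": rec.acronym, "crop": crop,
                       "country": country, "legacy": rec.meta.legacy,
                       "Q_CAM": qc, "Q_FAO": qf,
                       "endo_sum": endo.total}
                row.update({n: getattr(endo, n)
                            for n in ("Qy", "Qa", "Qs", "Qv", "Qr", "Qm",
                                      "Qd")})
                rows.append(row)
    return pd.DataFrame(rows)


def build_candidate_sets(world: TruthWorld,
                         harmonized: dict[str, dict[str, CropAreaGrid]],
                         scores: pd.DataFrame
                         ) -> dict[tuple[str, int], CandidateSet]:
    sets: dict[tuple[str, int], CandidateSet] = {}
    endo_by_ds = {rec.acronym: endogenous_scores(rec.meta)
                  for rec in world.datasets}
    for (crop, country), sub in scores.groupby(["crop", "country"]):
        cands = []
        for _, row in sub.iterrows():
            acr = row["dataset"]
            cands.append(Candidate(
                acronym=acr, endo=endo_by_ds[acr],
                q_cam=float(row["Q_CAM"]), q_fao=float(row["Q_FAO"]),
                legacy=bool(row["legacy"]),
                grid=harmonized[acr][crop]))
        sets[(crop, int(country))] = CandidateSet(crop, int(country), cands)
    return sets


def apply_gapfill(world: TruthWorld, mosaic: SelectionMosaic,
                  harmonized: dict[str, dict[str, CropAreaGrid]],
                  selections: list[SelectionResult]
                  ) -> dict[tuple[str, int], dict]:
    """Stage 5: fill every pair the selection routed to gap fill."""
    fao = _fao_lookup(world.fao_table)
    legacy_acr = next((r.acronym for r in world.datasets if r.meta.legacy),
                      None)
    codes = {rec.acronym: i + 1 for i, rec in enumerate(world.datasets)}
    reports: dict[tuple[str, int], dict] = {}
    for sel in selections:
        if sel.status != "gapfill":
            continue
        crop, country = sel.crop, sel.country
        legacy_grid = (harmonized[legacy_acr][crop]
                       if legacy_acr else None)
        filled, rep = gapfill_pair(
            crop, country, world.nso_tables.get(country), world.masks,
            world.cam, world.geometry.LA, legacy_grid)
        in_country = world.masks.country == country
        mosaic.crops[crop].HA[in_country] = filled.HA[in_country]
        mosaic.crops[crop].CA[in_country] = filled.CA[in_country]
        ha_total = float(filled.HA[in_country].sum())
        qual = gapfill_quality(NSO_ENDO, q_fao(ha_total,
                                               fao.get((crop, country))))
        nso_cells = in_country & np.isin(world.masks.subnational,
                                         rep["units_nso"])
        mosaic.qual[crop][in_country] = qual
        mosaic.set_map[crop][in_country & nso_cells] = NSO_CODE
        if legacy_acr:
            mosaic.set_map[crop][in_country & ~nso_cells] = codes[legacy_acr]
        mosaic.table.loc[(mosaic.table["crop"] == crop) &
                         (mosaic.table["country"] == country),
                         ["acronym", "Q"]] = ["NSO" if rep["units_nso"]
                                              else legacy_acr, qual]
        reports[(crop, country)] = rep
    return reports


def run_pipeline(world: TruthWorld, *, adjust: bool = True,
                 uncertainty_draws: int = 0,
                 seed: int = 0) -> PipelineResult:
    """Run all stages on a world and return every intermediate product."""
    harmonized = harmonize_all(world)
    scores = score_all(world, harmonized)
    candidate_sets = build_candidate_sets(world, harmonized, scores)
    selections = [select_best(cs) for _, cs in sorted(candidate_sets.items())]
    codes = {rec.acronym: i + 1 for i, rec in enumerate(world.datasets)}
    mosaic = build_mosaic(selections, candidate_sets, world.masks.country,
                          codes)
    result = PipelineResult(world, harmonized, scores, candidate_sets,
                            selections, mosaic)
    result.gapfill_reports = apply_gapfill(world, mosaic, harmonized,
                                           selections)
    if adjust:
        result.adjust_reports = adjust_mod.adjust_all(
            mosaic.crops, world.fao_table, world.masks.country,
            world.geometry.LA)
    # validation against withheld truth at the national level
    result.validation = validation_report(
        world.fao_table[["crop", "country", "harvested_area_ha"]],
        result.national_table(), on=["crop", "country"])
    total_CA = np.sum([g.CA for g in mosaic.crops.values()], axis=0)
    result.cam_report = cam_coverage(total_CA, world.cam)
    result.class_split = temporary_permanent_split(
        mosaic.crops, world.crop_registry, world.masks.country)
    if uncertainty_draws > 0:
        result.uncertainty = uncertainty_report(
            candidate_sets, n_draws=uncertainty_draws, seed=seed)
    return result
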