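"""Gap filling: disaggregation of subnational statistics over the
cropland-agreement percentile stack.

Pairs with no modern gridded candidate get their harvested area spread over
each subnational unit proportionally to the cropland-agreement map at a
percentile p iterated through {2.5, 5, 10, 25, 50}: iteration stops at the
first p at which some assigned cell falls below the 100 m^2 lower bound
(those cells are clamped to the bound); if no percentile triggers, the
median (p = 50) map is used.  Physical area is then capped by available
land and the 95th-percentile cropland surface, and HA is set equal to CA
(cropping intensity 1 is assumed for gap-filled cells).  Units without
subnational statistics fall back to the legacy layer unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .grid import CamStack, CropAreaGrid
from .harmonize import LOWER_BOUND_HA
from .quality import EndogenousScores

ITERATION_LEVELS = (2.5, 5.0, 10.0, 25.0, 50.0)


@dataclass
class DisaggregationResult:
    HA: np.ndarray            # over the whole grid, zero outside the unit
    percentile: float
    n_clamped: int
    residual_ha: float        # unit total minus the tabulated value

    def __post_init__(self) -> None:
        if self.n_clamped == 0 and abs(self.residual_ha) > 1e-6:
            raise ValueError("nonzero residual without clamped cells")


def disaggregate_unit(nso_value_ha: float, unit_mask: np.ndarray,
                      cam: CamStack) -> DisaggregationResult | None:
    """Spread one tabulated harvested-area value over a subnational unit.

    Returns None (with a warning) when the agreement map is zero over the
    unit at every percentile.
    """
    if nso_value_ha < 0:
        raise ValueError("tabulated harvested area must be non-negative")
    unit_mask = np.asarray(unit_mask, dtype=bool)
    chosen_level = None
    chosen_ha = None
    clamp_cells = None
    for lev in ITERATION_LEVELS:
        w = np.where(unit_mask, cam[lev], 0.0)
        total_w = w.sum()
        if total_w <= 0:
            continue
        ha = nso_value_ha * w / total_w
        below = (ha > 0) & (ha < LOWER_BOUND_HA)
        chosen_level, chosen_ha = lev, ha
        if np.any(below):
            clamp_cells = below
            break
        clamp_cells = None
    if chosen_level is None:
        warnings.warn("agreement map is zero over the unit at every "
                      "percentile; unit skipped", stacklevel=2)
        return None
    n_clamped = 0
    if clamp_cells is not None:
        chosen_ha = chosen_ha.copy()
        chosen_ha[clamp_cells] = LOWER_BOUND_HA
        n_clamped = int(np.count_nonzero(clamp_cells))
    residual = float(chosen_ha.sum() - nso_value_ha)
    if n_clamped == 0:
        residual = 0.0 if abs(residual) < 1e-6 else residual
    return DisaggregationResult(chosen_ha, chosen_level, n_clamped, residual)


def finalize_gapfill(HA: np.ndarray, LA: np.ndarray,
                     CAM95: np.ndarray, crop: str = "") -> CropAreaGrid:
    """Cap physical area by available land and the 95th-percentile cropland
    surface, then set HA = CA (cropping intensity 1)."""
    CA = np.minimum(np.minimum(HA, LA), CAM95)
    CA = np.clip(CA, 0.0, None)
    return CropAreaGrid(crop, CA.copy(), CA)


def fallback_legacy(legacy: CropAreaGrid,
                    region_mask: np.ndarray) -> CropAreaGrid:
    """Copy the legacy layer unchanged over a region (no statistics case)."""
    region_mask = np.asarray(region_mask, dtype=bool)
    return CropAreaGrid(legacy.crop,
                        np.where(region_mask, legacy.HA, 0.0),
                        np.where(region_mask, legacy.CA, 0.0))


def gapfill_quality(endo: EndogenousScores, q_fao: float) -> float:
    """Combined quality of a gap-filled layer: the spatial-agreement term is
    dropped (the agreement map itself did the spatialization), the
    remaining terms keep their weights, so the score lies in [0, 2/3]."""
    if not (0.0 <= q_fao <= 1.0):
        raise ValueError("Q_FAO outside [0, 1]")
    return float(endo.total / 21.0 + q_fao / 3.0)


def gapfill_pair(crop: str, country: int, nso_table, masks, cam: CamStack,
                 LA: np.ndarray,
                 legacy: CropAreaGrid | None) -> tuple[CropAreaGrid, dict]:
    """Gap-fill one (crop, country) pair.

    Units present in the subnational table are disaggregated and finalized;
    units absent from it (or with an all-zero agreement map) fall back to
    the legacy layer.  Returns the filled layers and a per-unit report.
    """
    in_country = masks.country == country
    shape = in_country.shape
    HA_nso = np.zeros(shape)
    nso_filled = np.zeros(shape, dtype=bool)
    report = {"units_nso": [], "units_legacy": [], "percentiles": {},
              "n_clamped": 0}

    covered_units = set()
    if nso_table is not None and len(nso_table):
        sub = nso_table[nso_table["crop"] == crop]
        for _, row in sub.iterrows():
            unit = int(row["unit"])
            unit_mask = masks.subnational == unit
            res = disaggregate_unit(float(row["harvested_area_ha"]),
                                    unit_mask, cam)
            if res is None:
                continue
            HA_nso += res.HA
            nso_filled |= unit_mask
            covered_units.add(unit)
            report["units_nso"].append(unit)
            report["percentiles"][unit] = res.percentile
            report["n_clamped"] += res.n_clamped

    filled = finalize_gapfill(HA_nso, LA, cam.cam95, crop)
    filled.HA[~nso_filled] = 0.0
    filled.CA[~nso_filled] = 0.0

    uncovered = in_country & ~nso_filled
    if np.any(uncovered) and legacy is not None:
        fb = fallback_legacy(legacy, uncovered)
        filled.HA += fb.HA
        filled.CA += fb.CA
        report["units_legacy"] = [u for u in masks.units_of(country)
                                  if u not in covered_units]
    return filled, report
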