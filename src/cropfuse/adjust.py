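"""National adjustment: scale each (crop, country) to its reference
harvested-area total under per-cell bounds.

One iteration applies, in fixed order: (1) a single multiplicative factor
per crop bringing the national HA total to the reference value, with CA
scaled by the same factor so the per-cell cropping intensity is preserved;
(2) the upper bound — where the all-crop sum of CA exceeds the available
land LA, the excess is removed proportionally to each crop's share of the
cell and redistributed in equal per-cell amounts to the crop's other
occupied cells with headroom; (3) the lower bound — cells with harvested
area below 100 m^2 are raised to the bound and the added area is removed
uniformly from the crop's other occupied cells.  Iteration stops after 60
rounds, or when the country's total differs from the reference by < 0.5%,
or when it changes by < 0.01% in a round.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import CropAreaGrid
from .harmonize import LOWER_BOUND_HA

MAX_ITERATIONS = 60
TOTAL_TOLERANCE = 0.005     # 0.5% distance from the reference total
CHANGE_TOLERANCE = 0.0001   # 0.01% relative change per iteration
_EPS = 1e-12


def _ci_map(grid: CropAreaGrid) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(grid.CA > 0, grid.HA / grid.CA, 1.0)


def scale_crop(grid: CropAreaGrid, target_ha: float,
               in_country: np.ndarray) -> float | None:
    """Apply one multiplicative factor to HA and CA over the country.

    Returns the factor, or None when the pair has no spatial support (zero
    current total with a positive target), in which case it is left
    untouched and reported unadjustable by the caller.
    """
    if target_ha < 0:
        raise ValueError("target harvested area must be non-negative")
    current = float(grid.HA[in_country].sum())
    if current <= 0:
        return None if target_ha > 0 else 1.0
    factor = target_ha / current
    grid.HA[in_country] *= factor
    grid.CA[in_country] *= factor
    return factor


def _spread_uniform(amount: float, eligible: np.ndarray,
                    capacity: np.ndarray) -> tuple[np.ndarray, float]:
    """Split ``amount`` into equal per-cell increments over eligible cells,
    capping each cell at its capacity and re-spreading the overshoot.
    Returns the per-cell allocation and the unallocated residual."""
    alloc = np.zeros_like(capacity)
    remaining = amount
    active = eligible & (capacity > _EPS)
    for _ in range(64):
        n = int(np.count_nonzero(active))
        if n == 0 or remaining <= _EPS:
            break
        inc = remaining / n
        room = capacity - alloc
        give = np.where(active, np.minimum(inc, room), 0.0)
        alloc += give
        remaining -= float(give.sum())
        active = active & (capacity - alloc > _EPS)
    return alloc, max(remaining, 0.0)


def enforce_upper_bound(crops: dict[str, CropAreaGrid], LA: np.ndarray,
                        in_country: np.ndarray) -> dict[str, float]:
    """Push the all-crop CA sum below LA everywhere in the country,
    conserving each crop's national total up to the returned residuals."""
    residuals: dict[str, float] = {}
    names = sorted(crops)
    ci = {c: _ci_map(crops[c]) for c in names}
    sum_ca = np.sum([crops[c].CA for c in names], axis=0)
    violating = in_country & (sum_ca > LA + _EPS)
    if not np.any(violating):
        return residuals
    excess = np.where(violating, sum_ca - LA, 0.0)
    removed: dict[str, float] = {}
    with np.errstate(invalid="ignore", divide="ignore"):
        for c in names:
            share = np.where(violating & (sum_ca > 0),
                             crops[c].CA / np.where(sum_ca > 0, sum_ca, 1.0),
                             0.0)
            cut = excess * share
            crops[c].CA -= cut
            crops[c].HA -= cut * ci[c]
            removed[c] = float(cut.sum())
    # redistribute each crop's removed area to its other occupied cells
    for c in names:
        if removed[c] <= _EPS:
            continue
        sum_ca = np.sum([crops[k].CA for k in names], axis=0)
        headroom = np.where(in_country, LA - sum_ca, 0.0)
        eligible = in_country & ~violating & (crops[c].CA > 0)
        alloc, residual = _spread_uniform(removed[c], eligible, headroom)
        crops[c].CA += alloc
        crops[c].HA += alloc * ci[c]
        if residual > 1e-9:
            residuals[c] = residual
    return residuals


def enforce_lower_bound(grid: CropAreaGrid, in_country: np.ndarray,
                        bound: float = LOWER_BOUND_HA) -> float:
    """Raise sub-bound cells to 100 m^2 (CA raised keeping CI) and remove
    the added area uniformly from the crop's other occupied cells without
    driving any below the bound.  Returns the unremovable residual."""
    ci = _ci_map(grid)
    occupied = in_country & (grid.HA > 0)
    below = occupied & (grid.HA < bound - _EPS)
    if not np.any(below):
        return 0.0
    added = float((bound - grid.HA[below]).sum())
    grid.HA[below] = bound
    grid.CA[below] = bound / ci[below]
    donors = occupied & ~below
    capacity = np.where(donors, grid.HA - bound, 0.0)
    alloc, residual = _spread_uniform(added, donors, capacity)
    grid.HA -= alloc
    grid.CA -= alloc / np.where(ci > 0, ci, 1.0)
    return residual


@dataclass
class AdjustmentReport:
    country: int
    iterations: int = 0
    converged: bool = False
    stop_reason: str = ""
    factors: dict[str, list[float]] = field(default_factory=dict)
    final_totals: dict[str, float] = field(default_factory=dict)
    targets: dict[str, float] = field(default_factory=dict)
    unadjustable: list[str] = field(default_factory=list)
    residuals: dict[str, float] = field(default_factory=dict)

    def final_factor(self, crop: str) -> float:
        """Cumulative adjustment factor applied to a crop."""
        return float(np.prod(self.factors.get(crop, [1.0])))


def adjust_country(crops: dict[str, CropAreaGrid], LA: np.ndarray,
                   in_country: np.ndarray, targets: dict[str, float],
                   max_iterations: int = MAX_ITERATIONS,
                   total_tolerance: float = TOTAL_TOLERANCE,
                   change_tolerance: float = CHANGE_TOLERANCE
                   ) -> AdjustmentReport:
    """Iteratively adjust all targeted crops in one country.

    ``crops`` maps crop id to layers (modified in place); only crops with a
    target are touched.
    """
    report = AdjustmentReport(country=-1, targets=dict(targets))
    active = {c: crops[c] for c in sorted(targets) if c in crops}
    target_total = sum(targets[c] for c in active)
    prev_total = None
    for it in range(1, max_iterations + 1):
        report.iterations = it
        for c, grid in active.items():
            f = scale_crop(grid, targets[c], in_country)
            if f is None:
                if c not in report.unadjustable:
                    report.unadjustable.append(c)
            else:
                report.factors.setdefault(c, []).append(f)
        res_up = enforce_upper_bound(active, LA, in_country)
        for c, r in res_up.items():
            report.residuals[c] = report.residuals.get(c, 0.0) + r
        for c, grid in active.items():
            r = enforce_lower_bound(grid, in_country)
            if r > 1e-9:
                report.residuals[c] = report.residuals.get(c, 0.0) + r
        total = sum(float(g.HA[in_country].sum()) for g in active.values())
        if target_total > 0 and \
                abs(total - target_total) / target_total < total_tolerance:
            report.converged = True
            report.stop_reason = "total within tolerance of reference"
            break
        if prev_total is not None and prev_total > 0 and \
                abs(total - prev_total) / prev_total < change_tolerance:
            report.converged = True
            report.stop_reason = "total change below tolerance"
            break
        if target_total == 0:
            report.converged = True
            report.stop_reason = "zero reference total"
            break
        prev_total = total
    else:
        report.stop_reason = "iteration cap reached"
    for c, grid in active.items():
        report.final_totals[c] = float(grid.HA[in_country].sum())
    return report


def adjust_all(crops: dict[str, CropAreaGrid], fao_table: pd.DataFrame,
               country_mask: np.ndarray, LA: np.ndarray,
               **kwargs) -> list[AdjustmentReport]:
    """Adjust every country present in the reference table; (crop, country)
    pairs absent from the table are left untouched."""
    reports = []
    for country, sub in fao_table.groupby("country"):
        targets = {row["crop"]: float(row["harvested_area_ha"])
                   for _, row in sub.iterrows() if row["crop"] in crops}
        if not targets:
            continue
        in_country = country_mask == country
        rep = adjust_country(crops, LA, in_country, targets, **kwargs)
        rep.country = int(country)
        reports.append(rep)
    return reports


def factor_table(reports: list[AdjustmentReport]) -> pd.DataFrame:
    """Cumulative adjustment factors per (country, crop) for diagnostics
    such as the share of pairs with factors outside [0.1, 10]."""
    rows = []
    for rep in reports:
        for crop in rep.targets:
            rows.append({"country": rep.country, "crop": crop,
                         "factor": rep.final_factor(crop),
                         "iterations": rep.iterations,
                         "converged": rep.converged})
    return pd.DataFrame(rows)
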