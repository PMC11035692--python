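"""Validation statistics: efficiency-style R², normalized RMSE, percent
error, the cropland-bounds coverage check, and the temporary/permanent
class split.

R² here is the Nash–Sutcliffe efficiency form — one minus the ratio of the
squared-error sum to the variance of the reference around its mean — and
may be negative for a predictor worse than the reference mean; it is
reported as-is.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import CamStack, CropAreaGrid, zonal_sum
from .harmonize import CropClassRegistry


def _paired(reference, predicted) -> tuple[np.ndarray, np.ndarray, int]:
    ref = np.asarray(reference, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if ref.shape != pred.shape:
        raise ValueError("reference and prediction differ in length")
    keep = np.isfinite(ref) & np.isfinite(pred)
    return ref[keep], pred[keep], int((~keep).sum())


def r_squared(reference, predicted) -> float:
    """Nash–Sutcliffe efficiency: 1 for a perfect match, 0 for the
    reference-mean null model, negative for worse."""
    ref, pred, _ = _paired(reference, predicted)
    if ref.size < 2:
        raise ValueError("need at least two paired records")
    ss_ref = float(((ref - ref.mean()) ** 2).sum())
    if ss_ref == 0:
        raise ValueError("reference has zero variance")
    return 1.0 - float(((ref - pred) ** 2).sum()) / ss_ref


def nrmse(reference, predicted) -> float:
    """RMSE normalized by the reference range (max minus min)."""
    ref, pred, _ = _paired(reference, predicted)
    if ref.size < 2:
        raise ValueError("need at least two paired records")
    rng = float(ref.max() - ref.min())
    if rng <= 0:
        raise ValueError("degenerate reference range")
    return float(np.sqrt(((ref - pred) ** 2).mean())) / rng


def percent_error(value: float, reference: float) -> float:
    """Signed percent departure of ``value`` from ``reference``."""
    if reference <= 0:
        raise ValueError("reference must be positive")
    return (value - reference) / reference * 100.0


@dataclass
class CamCoverageReport:
    n_cropped: int
    frac_on_cam: float      # cropped cells that are also CAM cropland
    frac_within: float      # within [5th, 95th] percentile bounds
    frac_below: float
    frac_above: float


def cam_coverage(total_CA: np.ndarray, cam: CamStack) -> CamCoverageReport:
    """Classify cropped cells (total CA > 0) against the 5th/95th-percentile
    cropland bounds; the three fractions partition the cropped set."""
    total_CA = np.asarray(total_CA, dtype=float)
    cropped = total_CA > 0
    n = int(np.count_nonzero(cropped))
    if n == 0:
        return CamCoverageReport(0, 0.0, 0.0, 0.0, 0.0)
    lo = cam[5.0][cropped]
    hi = cam[95.0][cropped]
    v = total_CA[cropped]
    below = v < lo
    above = v > hi
    within = ~below & ~above
    on_cam = cam.presence(95.0)[cropped]
    return CamCoverageReport(
        n_cropped=n,
        frac_on_cam=float(np.count_nonzero(on_cam)) / n,
        frac_within=float(np.count_nonzero(within)) / n,
        frac_below=float(np.count_nonzero(below)) / n,
        frac_above=float(np.count_nonzero(above)) / n,
    )


def temporary_permanent_split(crops: dict[str, CropAreaGrid],
                              registry: CropClassRegistry,
                              country_mask: np.ndarray) -> pd.DataFrame:
    """National physical-area totals split into temporary and permanent
    classes; every crop must be classified."""
    acc: dict[tuple[int, str], float] = {}
    for crop, grid in crops.items():
        cls = registry.crop_class(crop)
        for code, val in zonal_sum(grid.CA, country_mask).items():
            key = (int(code), cls)
            acc[key] = acc.get(key, 0.0) + float(val)
    rows = [{"country": c, "crop_class": k, "CA_ha": v}
            for (c, k), v in sorted(acc.items())]
    return pd.DataFrame(rows)


def validation_report(reference: pd.DataFrame, predicted: pd.DataFrame,
                      on: list[str], value: str = "harvested_area_ha"
                      ) -> pd.DataFrame:
    """Per-crop R² and NRMSE from two long-format tables joined on ``on``
    (e.g. ["crop", "country"]).  Records missing on either side are dropped
    pairwise and counted."""
    merged = reference.merge(predicted, on=on, suffixes=("_ref", "_pred"))
    rows = []
    for crop, sub in merged.groupby("crop"):
        ref = sub[f"{value}_ref"].to_numpy()
        pred = sub[f"{value}_pred"].to_numpy()
        n_dropped = (len(reference[reference["crop"] == crop]) - len(sub))
        row = {"crop": crop, "n": len(sub), "n_dropped": n_dropped}
        if len(sub) >= 2 and ref.max() > ref.min():
            row["R2"] = r_squared(ref, pred)
            row["NRMSE"] = nrmse(ref, pred)
        else:
            row["R2"] = np.nan
            row["NRMSE"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
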