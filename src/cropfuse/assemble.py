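"""Multi-criteria dataset selection and mosaic assembly.

For every (crop, country) pair the combined quality score

    Q = (Qy+Qa+Qs+Qv+Qr+Qm+Qd) / 21 + Q_CAM / 3 + Q_FAO / 3

ranks the candidate datasets; the legacy dataset is excluded from the
ranking, so a pair with only the legacy candidate is routed to the gap-fill
stage, and a single non-legacy candidate is selected automatically.  The
chosen layers are stitched into per-crop mosaic maps with a quality layer
(the winner's Q painted over the country) and an integer provenance layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import NO_DATA, CropAreaGrid
from .quality import EndogenousScores

#: provenance code reserved for pairs awaiting gap fill
GAPFILL_PENDING = 0

#: weight vector order: the seven endogenous indicators, then Q_CAM, Q_FAO
N_WEIGHTS = 9


@dataclass
class Candidate:
    """One dataset's scores and harmonized layers for a (crop, country)."""

    acronym: str
    endo: EndogenousScores
    q_cam: float
    q_fao: float
    legacy: bool = False
    grid: CropAreaGrid | None = None


@dataclass
class CandidateSet:
    crop: str
    country: int
    candidates: list[Candidate]

    def __post_init__(self) -> None:
        if not self.candidates:
            raise ValueError("candidate set must be non-empty")

    def non_legacy(self) -> list[Candidate]:
        return [c for c in self.candidates if not c.legacy]


def combined_score(endo: EndogenousScores, q_cam: float, q_fao: float,
                   weights: np.ndarray | None = None) -> float:
    """Combined quality score in [0, 1]; optional per-indicator weights
    multiply each indicator before the 1/3-1/3-1/3 combination."""
    q = np.concatenate([endo.as_array(), [q_cam, q_fao]])
    if weights is None:
        w = np.ones(N_WEIGHTS)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (N_WEIGHTS,):
            raise ValueError(f"expected {N_WEIGHTS} weights")
    wq = w * q
    score = wq[:7].sum() / 21.0 + wq[7] / 3.0 + wq[8] / 3.0
    return float(min(1.0, max(0.0, score)))


def _tie_key(c: Candidate) -> tuple:
    # deterministic tie-break: higher Qy first, then smallest acronym
    return (-c.endo.Qy, c.acronym)


@dataclass
class SelectionResult:
    crop: str
    country: int
    status: str                    # "selected" | "gapfill"
    acronym: str | None = None
    score: float | None = None
    scores: dict[str, float] = field(default_factory=dict)


def select_best(cs: CandidateSet,
                weights: np.ndarray | None = None) -> SelectionResult:
    """Pick the highest-scoring non-legacy candidate, or signal gap fill
    when only the legacy dataset covers the pair."""
    contenders = cs.non_legacy()
    if not contenders:
        return SelectionResult(cs.crop, cs.country, "gapfill")
    scores = {c.acronym: combined_score(c.endo, c.q_cam, c.q_fao, weights)
              for c in contenders}
    best = max(sorted(contenders, key=_tie_key),
               key=lambda c: scores[c.acronym])
    return SelectionResult(cs.crop, cs.country, "selected", best.acronym,
                           scores[best.acronym], scores)


@dataclass
class SelectionMosaic:
    """Fused per-crop layers plus per-crop quality and provenance maps."""

    crops: dict[str, CropAreaGrid]
    qual: dict[str, np.ndarray]
    set_map: dict[str, np.ndarray]
    table: pd.DataFrame            # crop, country, status, acronym, Q


def build_mosaic(selections: list[SelectionResult],
                 candidate_sets: dict[tuple[str, int], CandidateSet],
                 country_mask: np.ndarray,
                 dataset_codes: dict[str, int]) -> SelectionMosaic:
    """Stitch each country's winning layers into global per-crop maps.

    Gap-fill pairs are left empty with provenance code GAPFILL_PENDING for
    the gap-fill stage to overwrite.
    """
    crops = sorted({s.crop for s in selections})
    shape = country_mask.shape
    mosaic = {c: CropAreaGrid(c, np.zeros(shape), np.zeros(shape))
              for c in crops}
    qual = {c: np.full(shape, np.nan) for c in crops}
    set_map = {c: np.full(shape, NO_DATA, dtype=np.int32) for c in crops}
    rows = []
    for sel in selections:
        pair = (sel.crop, sel.country)
        in_country = country_mask == sel.country
        if sel.status == "gapfill":
            set_map[sel.crop][in_country] = GAPFILL_PENDING
            rows.append({"crop": sel.crop, "country": sel.country,
                         "status": "gapfill", "acronym": None, "Q": np.nan})
            continue
        cs = candidate_sets.get(pair)
        winner = next(c for c in cs.candidates if c.acronym == sel.acronym)
        if winner.grid is None:
            raise ValueError(f"candidate {sel.acronym} for {pair} has no "
                             "harmonized layers")
        mosaic[sel.crop].HA[in_country] = winner.grid.HA[in_country]
        mosaic[sel.crop].CA[in_country] = winner.grid.CA[in_country]
        qual[sel.crop][in_country] = sel.score
        set_map[sel.crop][in_country] = dataset_codes[sel.acronym]
        rows.append({"crop": sel.crop, "country": sel.country,
                     "status": "selected", "acronym": sel.acronym,
                     "Q": sel.score})
    table = pd.DataFrame(rows)
    return SelectionMosaic(mosaic, qual, set_map, table)
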