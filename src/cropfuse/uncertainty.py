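"""Monte-Carlo robustness of the multi-criteria selection.

The nine indicator weights (seven endogenous, two exogenous) are drawn from
independent Gaussian distributions with mean 1 and standard deviation 0.1,
truncated to [0.7, 1.3] (three standard deviations) by resampling, and the
frequency with which the weighted argmax differs from the unit-weight
selection is counted per (crop, country) pair with at least two non-legacy
candidates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .assemble import Candidate, CandidateSet, N_WEIGHTS, select_best

WEIGHT_MEAN = 1.0
WEIGHT_SD = 0.1
WEIGHT_LO = 0.7
WEIGHT_HI = 1.3
DEFAULT_N_DRAWS = 10_000

WEIGHT_NAMES = ("w_c", "w_a", "w_s", "w_v", "w_r", "w_m", "w_d",
                "w_C", "w_F")


def draw_weights(n: int, seed: int, mean: float = WEIGHT_MEAN,
                 sd: float = WEIGHT_SD, lo: float = WEIGHT_LO,
                 hi: float = WEIGHT_HI) -> np.ndarray:
    """n x 9 weight draws from a truncated normal.

    Truncation is by resampling out-of-range values (a proper truncated
    normal, with no probability atoms at the bounds).
    """
    if n < 1:
        raise ValueError("need at least one draw")
    rng = np.random.default_rng(seed)
    w = rng.normal(mean, sd, size=(n, N_WEIGHTS))
    bad = (w < lo) | (w > hi)
    while np.any(bad):
        w[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (w < lo) | (w > hi)
    return w


def _candidate_matrix(contenders: list[Candidate]) -> np.ndarray:
    """Per-candidate coefficient vectors so that score = clip(draws @ M)."""
    cols = []
    for c in contenders:
        q = np.concatenate([c.endo.as_array() / 21.0,
                            [c.q_cam / 3.0, c.q_fao / 3.0]])
        cols.append(q)
    return np.stack(cols, axis=1)  # (9, n_candidates)


def selection_change_frequency(cs: CandidateSet,
                               draws: np.ndarray) -> float:
    """Fraction of weight draws whose winner differs from the unit-weight
    winner, with the same deterministic tie-break (higher synchrony score,
    then smallest acronym)."""
    contenders = cs.non_legacy()
    if len(contenders) < 2:
        raise ValueError("need at least two non-legacy candidates")
    default = select_best(cs).acronym
    # order candidates by tie-break preference so argmax (first maximum)
    # reproduces the deterministic rule under score ties
    order = sorted(range(len(contenders)),
                   key=lambda i: (-contenders[i].endo.Qy,
                                  contenders[i].acronym))
    ordered = [contenders[i] for i in order]
    M = _candidate_matrix(ordered)
    scores = np.clip(draws @ M, 0.0, 1.0)
    winners = np.argmax(scores, axis=1)
    names = np.array([c.acronym for c in ordered])
    return float(np.mean(names[winners] != default))


@dataclass
class UncertaintyRecord:
    crop: str
    country: int
    default_winner: str
    change_frequency: float
    n_draws: int
    seed: int


def uncertainty_report(candidate_sets: dict[tuple[str, int], CandidateSet],
                       n_draws: int = DEFAULT_N_DRAWS,
                       seed: int = 0) -> pd.DataFrame:
    """Run the Monte-Carlo analysis over every pair with more than one
    non-legacy candidate; one shared weight matrix is used for all pairs."""
    draws = draw_weights(n_draws, seed)
    rows = []
    for (crop, country), cs in sorted(candidate_sets.items()):
        if len(cs.non_legacy()) < 2:
            continue
        freq = selection_change_frequency(cs, draws)
        rows.append(UncertaintyRecord(crop, country,
                                      select_best(cs).acronym, freq,
                                      n_draws, seed).__dict__)
    return pd.DataFrame(rows)
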