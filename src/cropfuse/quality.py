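"""Dataset quality indicators.

Two families of scores drive the multi-criteria dataset selection:

* *endogenous* indicators — seven per-dataset scores in [0, 1] computed from
  metadata alone: synchrony with the 2020 reference year (Qy), administrative
  scope (Qa), primary data source (Qs), validation level (Qv), spatial
  resolution (Qr), release maturity (Qm) and dispatch officiality (Qd);
* *exogenous* indicators — two scores per (dataset, crop, country):
  agreement of the crop's spatial support with the cropland-agreement map
  (Q_CAM) and relative error of the national harvested-area total against
  the reference statistics table (Q_FAO).

The shipped dataset registry stores indicator values as authoritative
overrides; the closed-form scoring functions are used for datasets added by
a user without explicit values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

REFERENCE_YEAR = 2020
R_MIN = 0.0000833  # finest input resolution, degrees
R_MAX = 0.0833     # coarsest input resolution, degrees

INDICATOR_NAMES = ("Qy", "Qa", "Qs", "Qv", "Qr", "Qm", "Qd")

_ADMIN_SCORES = {"national": 1.0, "multinational": 1.0, "global": 0.5}
_SOURCE_SCORES = {
    "survey+satellite+model": 1.0,
    "survey+satellite": 0.8,
    "survey+model": 0.7,
    "satellite+model": 0.5,
    "survey": 0.5,
    "satellite": 0.3,
    "model": 0.2,
}
_VALIDATION_SCORES = {"groundtruth": 1.0, "indirect": 0.5, "none": 0.0}
_MATURITY_SCORES = {"annual": 1.0, "periodic": 0.5, "never": 0.0}
_DISPATCH_SCORES = {"government": 1.0, "non-government": 0.5}


def q_synchrony(year: int, reference_year: int = REFERENCE_YEAR) -> float:
    """Synchrony score: 1 at the reference year, falling off linearly over
    ±20 years, clamped to [0, 1]."""
    if year < reference_year:
        q = (year - (reference_year - 20)) / 20.0
    elif year == reference_year:
        q = 1.0
    else:
        q = 1.0 - (year - reference_year) / 20.0
    return float(min(1.0, max(0.0, q)))


def q_admin(scope: str) -> float:
    try:
        return _ADMIN_SCORES[scope]
    except KeyError:
        raise ValueError(f"unknown administrative scope {scope!r}") from None


def q_source(method: str) -> float:
    try:
        return _SOURCE_SCORES[method]
    except KeyError:
        raise ValueError(f"unknown source method {method!r}") from None


def q_validation(level: str) -> float:
    try:
        return _VALIDATION_SCORES[level]
    except KeyError:
        raise ValueError(f"unknown validation level {level!r}") from None


def q_resolution(r: float, r_min: float = R_MIN, r_max: float = R_MAX) -> float:
    """Linear resolution score: 1 at the finest, 0 at the coarsest."""
    if not (r_min <= r <= r_max):
        warnings.warn(f"resolution {r} outside [{r_min}, {r_max}]; clamping",
                      stacklevel=2)
        r = min(r_max, max(r_min, r))
    return float(1.0 - (r - r_min) / (r_max - r_min))


def q_maturity(frequency: str) -> float:
    try:
        return _MATURITY_SCORES[frequency]
    except KeyError:
        raise ValueError(f"unknown maturity {frequency!r}") from None


def q_dispatch(officiality: str) -> float:
    try:
        return _DISPATCH_SCORES[officiality]
    except KeyError:
        raise ValueError(f"unknown dispatch {officiality!r}") from None


@dataclass
class DatasetMeta:
    """Registry metadata for one input dataset.

    ``overrides`` holds explicit indicator values that take precedence over
    the formula-derived ones; the shipped registry populates all seven.
    """

    acronym: str
    legacy: bool = False
    reference_year: int | None = None
    admin_scope: str | None = None
    source_method: str | None = None
    validation_level: str | None = None
    resolution_deg: float | None = None
    maturity: str | None = None
    dispatch: str | None = None
    overrides: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for k, v in self.overrides.items():
            if k not in INDICATOR_NAMES:
                raise ValueError(f"unknown indicator override {k!r}")
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"override {k}={v} outside [0, 1]")


@dataclass(frozen=True)
class EndogenousScores:
    Qy: float
    Qa: float
    Qs: float
    Qv: float
    Qr: float
    Qm: float
    Qd: float

    def __post_init__(self) -> None:
        for name in INDICATOR_NAMES:
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")

    @property
    def total(self) -> float:
        return sum(self.as_array())

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in INDICATOR_NAMES])


def endogenous_scores(meta: DatasetMeta) -> EndogenousScores:
    """Score a dataset on the seven endogenous indicators, preferring
    registry overrides over the closed-form expressions."""

    def resolve(name: str, value, formula) -> float:
        if name in meta.overrides:
            return meta.overrides[name]
        if value is None:
            raise ValueError(
                f"{meta.acronym}: no override and no metadata for {name}")
        return formula(value)

    return EndogenousScores(
        Qy=resolve("Qy", meta.reference_year, q_synchrony),
        Qa=resolve("Qa", meta.admin_scope, q_admin),
        Qs=resolve("Qs", meta.source_method, q_source),
        Qv=resolve("Qv", meta.validation_level, q_validation),
        Qr=resolve("Qr", meta.resolution_deg, q_resolution),
        Qm=resolve("Qm", meta.maturity, q_maturity),
        Qd=resolve("Qd", meta.dispatch, q_dispatch),
    )


# ---------------------------------------------------------------------------
# Registry I/O
# ---------------------------------------------------------------------------

def load_registry(path=None) -> dict[str, DatasetMeta]:
    """Load a dataset registry CSV; defaults to the packaged registry of the
    28 published input datasets with their printed indicator values."""
    if path is None:
        path = resources.files("cropfuse.data") / "dataset_registry.csv"
    df = pd.read_csv(path)
    registry: dict[str, DatasetMeta] = {}
    for _, row in df.iterrows():
        overrides = {n: float(row[n]) for n in INDICATOR_NAMES
                     if n in row and pd.notna(row[n])}
        registry[row["acronym"]] = DatasetMeta(
            acronym=row["acronym"],
            legacy=bool(int(row.get("legacy", 0) or 0)),
            reference_year=(int(row["reference_year"])
                            if pd.notna(row.get("reference_year")) else None),
            admin_scope=(row["admin_scope"]
                         if pd.notna(row.get("admin_scope")) else None),
            source_method=(row["source_method"]
                           if pd.notna(row.get("source_method")) else None),
            validation_level=(row["validation_level"]
                              if pd.notna(row.get("validation_level")) else None),
            resolution_deg=(float(row["resolution_deg"])
                            if pd.notna(row.get("resolution_deg")) else None),
            maturity=(row["maturity"]
                      if pd.notna(row.get("maturity")) else None),
            dispatch=(row["dispatch"]
                      if pd.notna(row.get("dispatch")) else None),
            overrides=overrides,
        )
    return registry


# ---------------------------------------------------------------------------
# Exogenous indicators
# ---------------------------------------------------------------------------

def q_cam(CA: np.ndarray, cam_presence: np.ndarray, country_mask: np.ndarray,
          country_code: int) -> float:
    """Spatial-agreement score: the fraction of the dataset's cropped cells
    (CA > 0) inside the country that are also cropland in the agreement
    map.  A crop absent from the dataset in that country scores 0."""
    in_country = country_mask == country_code
    cropped = in_country & (np.asarray(CA) > 0)
    n_ca = int(np.count_nonzero(cropped))
    if n_ca == 0:
        return 0.0
    n_overlap = int(np.count_nonzero(cropped & np.asarray(cam_presence)))
    return n_overlap / n_ca


def q_fao(ha_total: float, ha_reference: float | None) -> float:
    """Statistics-agreement score: one minus the capped relative error of
    the dataset's national total against the reference table.  Pairs absent
    from the table score 0."""
    if ha_reference is None:
        return 0.0
    if ha_total < 0 or ha_reference < 0:
        raise ValueError("harvested-area totals must be non-negative")
    if ha_reference == 0:
        return 1.0 if ha_total == 0 else 0.0
    return 1.0 - min(1.0, abs(ha_total - ha_reference) / ha_reference)
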