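"""Input harmonization: every raw layer, whatever its variable convention
(harvested area HA, physical area CA, cover fraction f, binary presence w)
and resolution, becomes an (HA, CA) pair in hectares on the common grid.

Rules applied, in order:

* binary presence at fine resolution -> cover fraction by pixel counting;
* fraction -> CA = f * GA, HA = CA;
* HA-only -> CA = HA (permanent crops) or min{HA, LA, CAM95} (temporary);
* CA with a cropping-intensity map -> HA = CA * CI;
* multi-season layers -> annual CA = max over seasons, HA = sum;
* conservative (mass-preserving) regridding of area layers;
* lower bound: both layers zeroed where CA < 0.01 ha (100 m^2);
* consistency diagnostics: CA <= HA, CA <= LA <= GA, CI <= 3.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import GridSpec, CellGeometry, CamStack, CropAreaGrid

LOWER_BOUND_HA = 0.01  # 100 m^2 in hectares
CI_MAX = 3.0

VARIABLE_KINDS = ("ha", "ha_ca", "ca", "f", "w")


@dataclass
class RawLayer:
    """One crop's raw layer(s) from an input dataset, on the source grid.

    ``values`` is a single 2-D array for kinds ha/ha_ca/ca/f, or is ignored
    when ``seasons`` (a list of per-season arrays) is given.  ``values2``
    carries CA when kind == "ha_ca".
    """

    crop: str
    kind: str
    spec: GridSpec
    values: np.ndarray | None = None
    values2: np.ndarray | None = None
    seasons: list[np.ndarray] | None = None
    ci: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.kind not in VARIABLE_KINDS:
            raise ValueError(f"unknown variable kind {self.kind!r}")
        arrays = self.seasons if self.seasons is not None else [self.values]
        for a in arrays:
            a = np.asarray(a)
            if self.kind == "f" and np.any((a < 0) | (a > 1)):
                raise ValueError("fraction layer outside [0, 1]")
            if self.kind == "w" and not np.isin(a, (0, 1)).all():
                raise ValueError("binary layer must be 0/1")
            if self.kind in ("ha", "ha_ca", "ca") and np.any(a < 0):
                raise ValueError("area layer must be non-negative")
        if self.ci is not None and np.any((self.ci < 0) | (self.ci > CI_MAX)):
            raise ValueError(f"cropping intensity outside [0, {CI_MAX}]")


class CropClassRegistry:
    """Canonical crop ids, temporary/permanent class, and source-name
    aggregation (several source crop names may map to one canonical crop)."""

    def __init__(self, classes: dict[str, str],
                 aggregation: dict[str, str] | None = None):
        for crop, cls in classes.items():
            if cls not in ("temporary", "permanent"):
                raise ValueError(f"crop {crop!r} has unknown class {cls!r}")
        self.classes = dict(classes)
        self.aggregation = dict(aggregation or {})

    @classmethod
    def from_csv(cls, path) -> "CropClassRegistry":
        df = pd.read_csv(path)
        classes = {}
        agg = {}
        for _, row in df.iterrows():
            canonical = row["canonical_crop"]
            classes[canonical] = row["crop_class"]
            src = row.get("source_name")
            if pd.notna(src):
                agg[src] = canonical
        return cls(classes, agg)

    def canonical(self, source_name: str) -> str:
        return self.aggregation.get(source_name, source_name)

    def crop_class(self, crop: str) -> str:
        try:
            return self.classes[crop]
        except KeyError:
            raise ValueError(f"crop {crop!r} missing from class registry") \
                from None


# ---------------------------------------------------------------------------
# Elementary conversions
# ---------------------------------------------------------------------------

def binary_to_fraction(w: np.ndarray, fine_spec: GridSpec,
                       common_spec: GridSpec) -> np.ndarray:
    """Cover fraction on the common grid by counting fine presence pixels.

    Fine pixels are assigned to the common cell containing their centre;
    when the fine grid nests exactly this is plain block counting.
    """
    w = np.asarray(w, dtype=float)
    if fine_spec.resolution > common_spec.resolution + 1e-12:
        raise ValueError("binary layer is coarser than the common grid")
    ratio = common_spec.resolution / fine_spec.resolution
    if abs(ratio - round(ratio)) < 1e-9 and \
            fine_spec.shape == (common_spec.n_rows * round(ratio),
                                common_spec.n_cols * round(ratio)):
        k = round(ratio)
        blocks = w.reshape(common_spec.n_rows, k, common_spec.n_cols, k)
        return blocks.mean(axis=(1, 3))
    # general case: assign each fine pixel by its centre coordinates
    lat = fine_spec.lat_centers()
    lon = fine_spec.lon_centers()
    rows = np.floor((common_spec.lat_max - lat) /
                    common_spec.resolution).astype(int)
    cols = np.floor((lon - common_spec.lon_min) /
                    common_spec.resolution).astype(int)
    rows = np.clip(rows, 0, common_spec.n_rows - 1)
    cols = np.clip(cols, 0, common_spec.n_cols - 1)
    ones = np.zeros(common_spec.shape)
    total = np.zeros(common_spec.shape)
    rr = np.repeat(rows, len(cols))
    cc = np.tile(cols, len(rows))
    np.add.at(ones, (rr, cc), w.ravel())
    np.add.at(total, (rr, cc), 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(total > 0, ones / total, 0.0)
    return f


def fraction_to_areas(f: np.ndarray, GA: np.ndarray
                      ) -> tuple[np.ndarray, np.ndarray]:
    """CA = f * GA; HA imputed equal to CA (single harvest assumed)."""
    f = np.asarray(f, dtype=float)
    if np.any((f < 0) | (f > 1)):
        raise ValueError("fraction outside [0, 1]")
    CA = f * GA
    return CA, CA.copy()


def impute_CA_from_HA(HA: np.ndarray, crop_class: str, LA: np.ndarray,
                      CAM95: np.ndarray) -> np.ndarray:
    """Physical area from harvested area: identity for permanent crops,
    capped by available land and the 95th-percentile cropland surface for
    temporary crops."""
    if crop_class == "permanent":
        return np.asarray(HA, dtype=float).copy()
    if crop_class == "temporary":
        return np.minimum(np.minimum(HA, LA), CAM95)
    raise ValueError(f"unknown crop class {crop_class!r}")


def combine_seasons(season_CAs: list[np.ndarray]
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Annual CA is the cell-wise max over seasons, HA the cell-wise sum."""
    if not season_CAs:
        raise ValueError("need at least one season")
    stack = np.stack([np.asarray(s, dtype=float) for s in season_CAs])
    return stack.max(axis=0), stack.sum(axis=0)


def apply_intensity(CA: np.ndarray, CI: np.ndarray) -> np.ndarray:
    """HA = CA * CI where a geo-referenced cropping intensity is given."""
    CI = np.asarray(CI, dtype=float)
    if np.any((CI < 0) | (CI > CI_MAX)):
        raise ValueError(f"cropping intensity outside [0, {CI_MAX}]")
    return np.asarray(CA, dtype=float) * CI


def _overlap_weights(src_edges: np.ndarray, dst_edges: np.ndarray,
                     transform=None) -> np.ndarray:
    """Fraction of each source interval falling in each destination
    interval, optionally in a transformed (area-true) coordinate."""
    s = np.asarray(src_edges, dtype=float)
    d = np.asarray(dst_edges, dtype=float)
    if transform is not None:
        s, d = transform(s), transform(d)
    # force ascending intervals
    if s[0] > s[-1]:
        s = s[::-1]
        flip_s = True
    else:
        flip_s = False
    if d[0] > d[-1]:
        d = d[::-1]
        flip_d = True
    else:
        flip_d = False
    lo = np.maximum(s[:-1, None], d[None, :-1])
    hi = np.minimum(s[1:, None], d[None, 1:])
    ov = np.clip(hi - lo, 0.0, None)
    width = (s[1:] - s[:-1])[:, None]
    W = ov / width
    if flip_s:
        W = W[::-1, :]
    if flip_d:
        W = W[:, ::-1]
    return W


def resample_conservative(layer: np.ndarray, src: GridSpec,
                          dst: GridSpec) -> np.ndarray:
    """Regrid an extensive (area) layer by exact fractional overlap.

    Each source cell's content is split among destination cells in
    proportion to geometric overlap measured in (sin lat, lon), so the
    global total is conserved to machine precision.
    """
    for a, b in ((src.lon_min, dst.lon_min), (src.lon_max, dst.lon_max),
                 (src.lat_min, dst.lat_min), (src.lat_max, dst.lat_max)):
        if abs(a - b) > 1e-9:
            raise ValueError("source and destination grids must share bounds")
    layer = np.asarray(layer, dtype=float)
    if layer.shape != src.shape:
        raise ValueError("layer shape does not match source grid")
    if src.resolution == dst.resolution:
        return layer.copy()
    Wlat = _overlap_weights(src.lat_edges(), dst.lat_edges(),
                            transform=lambda x: np.sin(np.deg2rad(x)))
    Wlon = _overlap_weights(src.lon_edges(), dst.lon_edges())
    out = Wlat.T @ layer @ Wlon
    return np.clip(out, 0.0, None)


def apply_lower_bound(CA: np.ndarray, HA: np.ndarray,
                      bound: float = LOWER_BOUND_HA
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Zero both layers wherever CA falls below 100 m^2 (0.01 ha)."""
    CA = np.asarray(CA, dtype=float).copy()
    HA = np.asarray(HA, dtype=float).copy()
    tiny = CA < bound
    CA[tiny] = 0.0
    HA[tiny] = 0.0
    return CA, HA


@dataclass
class ConsistencyReport:
    """Per-rule lists of violating cell indices; empty means all rules hold."""

    violations: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not any(self.violations.values())

    def count(self) -> int:
        return sum(len(v) for v in self.violations.values())


def consistency_check(grid: CropAreaGrid, LA: np.ndarray, GA: np.ndarray,
                      atol: float = 1e-6) -> ConsistencyReport:
    """Diagnose violations of CA <= HA, CA <= LA <= GA and CI <= 3."""
    rep = ConsistencyReport()

    def flag(rule: str, bad: np.ndarray) -> None:
        idx = np.argwhere(bad)
        if idx.size:
            rep.violations[rule] = [tuple(map(int, ij)) for ij in idx]

    HA, CA = grid.HA, grid.CA
    flag("CA<=HA", CA - HA > atol)
    flag("CA<=LA", CA - LA > atol)
    flag("LA<=GA", LA - GA > atol)
    flag("CA>=0", CA < -atol)
    flag("HA>=0", HA < -atol)
    with np.errstate(invalid="ignore", divide="ignore"):
        ci = np.where(CA > 0, HA / CA, 1.0)
    flag("CI<=3", ci > CI_MAX + 1e-9)
    return rep


# ---------------------------------------------------------------------------
# Whole-dataset harmonization
# ---------------------------------------------------------------------------

def harmonize_layer(raw: RawLayer, common: GridSpec, geometry: CellGeometry,
                    cam: CamStack, registry: CropClassRegistry,
                    GA: np.ndarray | None = None) -> CropAreaGrid:
    """Run one raw layer through the full Step-1 rule chain and return the
    harmonized (HA, CA) pair on the common grid."""
    GA = geometry.GA if GA is None else GA
    crop = registry.canonical(raw.crop)
    crop_class = registry.crop_class(crop)

    def to_common(area_layer: np.ndarray) -> np.ndarray:
        if raw.spec.resolution == common.resolution:
            return np.asarray(area_layer, dtype=float).copy()
        return resample_conservative(area_layer, raw.spec, common)

    if raw.kind == "w":
        if raw.seasons is not None:
            season_CAs = []
            for w in raw.seasons:
                f = binary_to_fraction(w, raw.spec, common)
                ca, _ = fraction_to_areas(f, GA)
                season_CAs.append(ca)
            CA, HA = combine_seasons(season_CAs)
        else:
            f = binary_to_fraction(raw.values, raw.spec, common)
            CA, HA = fraction_to_areas(f, GA)
    elif raw.kind == "f":
        if raw.spec.resolution == common.resolution:
            f = np.asarray(raw.values, dtype=float)
            CA, HA = fraction_to_areas(f, GA)
        else:
            # convert to area on the source grid first, then regrid
            from .grid import cell_area
            src_CA = np.asarray(raw.values, dtype=float) * cell_area(raw.spec)
            CA = to_common(src_CA)
            HA = CA.copy()
    elif raw.kind == "ha":
        HA = to_common(raw.values)
        CA = impute_CA_from_HA(HA, crop_class, geometry.LA, cam.cam95)
    elif raw.kind == "ca":
        CA = to_common(raw.values)
        HA = apply_intensity(CA, raw.ci) if raw.ci is not None else CA.copy()
    elif raw.kind == "ha_ca":
        HA = to_common(raw.values)
        CA = to_common(raw.values2)
    else:  # pragma: no cover - guarded by RawLayer validation
        raise ValueError(raw.kind)

    HA = np.maximum(HA, CA)  # CI >= 1 wherever the crop is present
    # physical area cannot exceed the land available for cropping; scale
    # both layers down together so the cell's cropping intensity survives
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(CA > geometry.LA,
                         np.where(CA > 0, geometry.LA / np.where(CA > 0, CA, 1.0), 1.0),
                         1.0)
    CA = CA * ratio
    HA = HA * ratio
    CA, HA = apply_lower_bound(CA, HA)
    return CropAreaGrid(crop, HA, CA)
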