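"""Suitability thresholding, tier classification, and multi-species compositing.

Suitability tiers follow the standard four-class scheme: non-suitable
(P < 0.2), low (0.2 <= P < 0.4), medium (0.4 <= P < 0.6) and high (P >= 0.6);
habitat is every tier >= low.  Composite maps take the per-cell maximum over
species, and each habitat cell inherits the functional class of its best
(argmax) species.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SpeciesCatalog", "TierMap", "CompositeMap", "DEFAULT_TIER_CUTS",
           "max_sss_threshold", "classify_tiers", "binary_habitat",
           "aggregate_species", "apply_mask"]

DEFAULT_TIER_CUTS = (0.2, 0.4, 0.6)

FUNCTIONAL_CLASSES = ("productive", "wildlife")


@dataclass
class SpeciesCatalog:
    """species_id -> (vegetation_type, functional_class), in a fixed order.

    The row order is the tie-break order for argmax assignment in
    :func:`aggregate_species`.
    """

    table: pd.DataFrame   # columns: species_id, vegetation_type, functional_class

    def __post_init__(self):
        need = {"species_id", "vegetation_type", "functional_class"}
        missing = need - set(self.table.columns)
        if missing:
            raise ValueError(f"catalog missing columns {sorted(missing)}")
        bad = set(self.table["functional_class"]) - set(FUNCTIONAL_CLASSES)
        if bad:
            raise ValueError(f"unknown functional classes {sorted(bad)}")
        if self.table["species_id"].duplicated().any():
            raise ValueError("duplicate species_id in catalog")
        t2c = self.table.groupby("vegetation_type")["functional_class"].nunique()
        if (t2c > 1).any():
            raise ValueError("a vegetation type maps to more than one functional class")
        self.table = self.table.reset_index(drop=True)

    @property
    def species_ids(self) -> list[str]:
        return list(self.table["species_id"])

    def functional_class(self, species_id: str) -> str:
        row = self.table[self.table["species_id"] == species_id]
        if row.empty:
            raise KeyError(species_id)
        return row["functional_class"].iloc[0]

    def vegetation_type(self, species_id: str) -> int:
        row = self.table[self.table["species_id"] == species_id]
        if row.empty:
            raise KeyError(species_id)
        return int(row["vegetation_type"].iloc[0])

    def to_csv(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SpeciesCatalog":
        return cls(pd.read_csv(path, dtype={"species_id": str}))


def max_sss_threshold(presence_pred, background_pred) -> float:
    """Threshold maximizing sensitivity + specificity.

    Candidates are the sorted unique predicted values; sensitivity(t) is the
    fraction of presences >= t, specificity(t) the fraction of background < t.
    Ties return the smallest maximizing threshold.
    """
    p = np.sort(np.asarray(presence_pred, dtype=float))
    b = np.sort(np.asarray(background_pred, dtype=float))
    if p.size == 0 or b.size == 0:
        raise ValueError("both prediction sets must be non-empty")
    cand = np.unique(np.concatenate([p, b]))
    # integer scoring (sens + spec over the common denominator n_p * n_b)
    # keeps exact ties exact, so the smallest maximizing threshold wins
    n_pres_ge = p.size - np.searchsorted(p, cand, side="left")
    n_bg_lt = np.searchsorted(b, cand, side="left")
    score = n_pres_ge * b.size + n_bg_lt * p.size
    return float(cand[np.argmax(score)])


@dataclass
class TierMap:
    """Per-cell suitability tier: -1 nodata, 0 non-suitable, 1 low, 2 medium, 3 high."""

    tiers: np.ndarray
    cuts: tuple[float, float, float] = DEFAULT_TIER_CUTS

    def counts(self) -> dict[int, int]:
        return {t: int((self.tiers == t).sum()) for t in (0, 1, 2, 3)}

    @property
    def valid(self) -> np.ndarray:
        return self.tiers >= 0


def classify_tiers(suit: np.ndarray, cuts=DEFAULT_TIER_CUTS) -> TierMap:
    """Classify a suitability raster in [0, 1] into the four tiers.

    Boundaries are left-inclusive (P = 0.2 is low, P = 0.6 is high); nodata
    (NaN) propagates as tier -1.
    """
    suit = np.asarray(suit, dtype=float)
    valid = np.isfinite(suit)
    vals = suit[valid]
    if vals.size and (vals.min() < -1e-9 or vals.max() > 1 + 1e-9):
        raise ValueError("suitability values outside [0, 1]")
    if not (0 < cuts[0] < cuts[1] < cuts[2] < 1):
        raise ValueError("tier cutpoints must be strictly increasing in (0, 1)")
    tiers = np.full(suit.shape, -1, dtype=np.int8)
    tiers[valid] = np.digitize(vals, cuts, right=False)
    return TierMap(tiers, tuple(cuts))


def binary_habitat(tiers: TierMap) -> np.ndarray:
    """Habitat presence (tier >= low) as float 0/1 with NaN nodata."""
    out = np.where(tiers.tiers >= 1, 1.0, 0.0)
    out[tiers.tiers < 0] = np.nan
    return out


@dataclass
class CompositeMap:
    """Multi-species composite: max suitability, best species, habitat, class.

    ``argmax`` holds catalog row indices (-1 on nodata); ``functional`` is
    0 = non-grassland, 1 = productive, 2 = wildlife.
    """

    composite: np.ndarray
    argmax: np.ndarray
    grassland: np.ndarray           # float 0/1 with NaN nodata
    functional: np.ndarray          # int8
    catalog: SpeciesCatalog
    habitat_cut: float = DEFAULT_TIER_CUTS[0]

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.composite)

    def class_binary(self, functional_class: str) -> np.ndarray:
        code = FUNCTIONAL_CLASSES.index(functional_class) + 1
        out = np.where(self.functional == code, 1.0, 0.0)
        out[~self.valid] = np.nan
        return out


def aggregate_species(suits: dict[str, np.ndarray], catalog: SpeciesCatalog,
                      habitat_cut: float = DEFAULT_TIER_CUTS[0]) -> CompositeMap:
    """Aggregate per-species suitability maps into one composite map.

    Per cell: composite = max over species; the attaining (argmax) species —
    ties resolved by catalog order — supplies the functional class; grassland
    is composite >= ``habitat_cut``.
    """
    order = [s for s in catalog.species_ids if s in suits]
    if not order:
        raise ValueError("no species maps match the catalog")
    shapes = {suits[s].shape for s in order}
    if len(shapes) != 1:
        raise ValueError("species maps do not share geometry")
    stack = np.stack([suits[s] for s in order])
    valid = np.all(np.isfinite(stack), axis=0)
    composite = np.full(stack.shape[1:], np.nan)
    composite[valid] = np.max(stack[:, valid], axis=0)
    am = np.argmax(stack, axis=0)            # first max -> catalog order tie-break
    argmax = np.where(valid, am, -1)
    grass = np.where(composite >= habitat_cut, 1.0, 0.0)
    grass[~valid] = np.nan
    class_codes = np.array(
        [FUNCTIONAL_CLASSES.index(catalog.functional_class(s)) + 1 for s in order],
        dtype=np.int8)
    functional = np.zeros(stack.shape[1:], dtype=np.int8)
    on = valid & (grass == 1.0)
    functional[on] = class_codes[am[on]]
    cat_rows = np.array([catalog.species_ids.index(s) for s in order])
    argmax = np.where(argmax >= 0, cat_rows[np.clip(am, 0, None)], -1)
    return CompositeMap(composite, argmax.astype(np.int32), grass, functional,
                        catalog, habitat_cut)


def apply_mask(obj, mask: np.ndarray):
    """Remove excluded cells (mask == 1) before any area accounting.

    Works on a plain raster (excluded cells -> NaN) or a
    :class:`CompositeMap` (excluded cells -> nodata everywhere).
    """
    mask = np.asarray(mask, dtype=float)
    excluded = mask == 1.0
    if isinstance(obj, CompositeMap):
        if mask.shape != obj.composite.shape:
            raise ValueError("mask geometry mismatch")
        comp = obj.composite.copy()
        comp[excluded] = np.nan
        grass = obj.grassland.copy()
        grass[excluded] = np.nan
        argmax = obj.argmax.copy()
        argmax[excluded] = -1
        functional = obj.functional.copy()
        functional[excluded] = 0
        return CompositeMap(comp, argmax, grass, functional, obj.catalog,
                            obj.habitat_cut)
    arr = np.asarray(obj, dtype=float)
    if mask.shape != arr.shape:
        raise ValueError("mask geometry mismatch")
    out = arr.copy()
    out[excluded] = np.nan
    return out
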