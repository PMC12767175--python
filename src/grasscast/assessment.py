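"""Validation against a survey map, area accounting, and scenario change summaries."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .composite import CompositeMap, FUNCTIONAL_CLASSES, SpeciesCatalog
from .rasters import GridGeometry

__all__ = ["ConfusionMap", "ChangeSummary", "KM_PER_DEGREE",
           "confusion_map", "concordance", "area_of", "change_summary",
           "functional_change"]

#: kilometres per degree of a great circle (spherical Earth approximation)
KM_PER_DEGREE = 111.195

# confusion map cell codes
CONSISTENT_NON = 0
CONCORDANT = 1
COMMISSION = 2
OMISSION = 3


@dataclass
class ConfusionMap:
    """Cellwise model-vs-survey cross-classification.

    Codes: 0 consistent non-grassland, 1 concordant grassland,
    2 commission (model only), 3 omission (survey only); -1 nodata.
    """

    classes: np.ndarray

    def counts(self) -> dict[str, int]:
        c = self.classes
        return {
            "concordant_grassland": int((c == CONCORDANT).sum()),
            "commission": int((c == COMMISSION).sum()),
            "omission": int((c == OMISSION).sum()),
            "consistent_non_grassland": int((c == CONSISTENT_NON).sum()),
        }

    @property
    def n_valid(self) -> int:
        return int((self.classes >= 0).sum())


def confusion_map(model: np.ndarray, survey: np.ndarray) -> ConfusionMap:
    """Cross-classify two binary maps (NaN = nodata) into the four classes."""
    model = np.asarray(model, dtype=float)
    survey = np.asarray(survey, dtype=float)
    if model.shape != survey.shape:
        raise ValueError("model/survey geometry mismatch")
    valid = np.isfinite(model) & np.isfinite(survey)
    out = np.full(model.shape, -1, dtype=np.int8)
    m = model == 1.0
    s = survey == 1.0
    out[valid & m & s] = CONCORDANT
    out[valid & m & ~s] = COMMISSION
    out[valid & ~m & s] = OMISSION
    out[valid & ~m & ~s] = CONSISTENT_NON
    return ConfusionMap(out)


def concordance(conf: ConfusionMap) -> dict[str, float]:
    """Agreement percentages from a confusion map.

    ``overall_agreement``: (concordant + consistent non) / valid cells — the
    headline concordance.  ``grassland_union_agreement``: concordant /
    (concordant + commission + omission).  Both in %, rounded to 2 decimals.
    """
    c = conf.counts()
    n = conf.n_valid
    if n == 0:
        raise ValueError("no valid cells")
    overall = 100.0 * (c["concordant_grassland"] + c["consistent_non_grassland"]) / n
    union = c["concordant_grassland"] + c["commission"] + c["omission"]
    union_pct = 100.0 * c["concordant_grassland"] / union if union else 100.0
    return {"overall_agreement": round(overall, 2),
            "grassland_union_agreement": round(union_pct, 2)}


def area_of(binary: np.ndarray, geom: GridGeometry, geographic: bool = False,
            cell_size_km: float | None = None) -> float:
    """Area of the 1-cells of a binary map, in 10^4 km^2.

    Planar mode: count x (cell_size_km)^2, with ``cell_size_km`` defaulting to
    the geometry's cell size.  Geographic mode: cells are (cell_size_deg x
    111.195 km)^2 scaled by cos(latitude) of each cell-center row.
    """
    binary = np.asarray(binary, dtype=float)
    if binary.shape != geom.shape:
        raise ValueError("map/geometry shape mismatch")
    ones = binary == 1.0
    if geographic:
        lat = geom.row_latitudes()
        cell_km2 = (geom.cell_size * KM_PER_DEGREE) ** 2 * np.cos(np.radians(lat))
        total = float((ones.sum(axis=1) * cell_km2).sum())
    else:
        cs = geom.cell_size if cell_size_km is None else cell_size_km
        total = float(ones.sum()) * cs**2
    return total / 1e4


@dataclass
class ChangeSummary:
    """Per-scenario grassland area accounting (the Table-1-style summary).

    Percentages are computed from unrounded areas and rounded to 2 decimals
    only at report time.
    """

    table: pd.DataFrame   # scenario, area_1e4km2, share_pct, change_pct

    def rounded(self) -> pd.DataFrame:
        out = self.table.copy()
        for col in ("area_1e4km2", "share_pct", "change_pct"):
            out[col] = out[col].round(2)
        return out

    def to_csv(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        self.rounded().to_csv(path, index=False, float_format="%.2f")

    def __str__(self) -> str:
        return self.rounded().to_string(index=False, float_format="%.2f".__mod__)

    def plot(self, ax=None):
        """Bar chart of percent change per scenario."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        rows = self.table.dropna(subset=["change_pct"])
        ax.bar(rows["scenario"], rows["change_pct"])
        ax.axhline(0, color="k", lw=0.8)
        ax.set_ylabel("change vs baseline (%)")
        return ax


def change_summary(baseline_area: float, scenario_areas: dict[str, float],
                   land_area: float) -> ChangeSummary:
    """Baseline + per-scenario areas -> shares, changes, and a scenario mean.

    ``change_pct`` is 100 x (A_s - A_baseline) / A_baseline; ``share_pct`` is
    100 x A / land_area; the mean row averages the scenario areas.
    """
    if land_area <= 0:
        raise ValueError("land area must be positive")
    if baseline_area <= 0:
        raise ValueError("baseline area must be positive")
    if any(a < 0 for a in scenario_areas.values()):
        raise ValueError("areas must be non-negative")
    rows = [{"scenario": "baseline", "area_1e4km2": baseline_area,
             "share_pct": 100.0 * baseline_area / land_area, "change_pct": np.nan}]
    for sc, a in scenario_areas.items():
        rows.append({"scenario": sc, "area_1e4km2": a,
                     "share_pct": 100.0 * a / land_area,
                     "change_pct": 100.0 * (a - baseline_area) / baseline_area})
    if scenario_areas:
        mean_a = float(np.mean(list(scenario_areas.values())))
        rows.append({"scenario": "mean", "area_1e4km2": mean_a,
                     "share_pct": 100.0 * mean_a / land_area,
                     "change_pct": 100.0 * (mean_a - baseline_area) / baseline_area})
    return ChangeSummary(pd.DataFrame(rows))


def functional_change(baseline: CompositeMap, scenarios: dict[str, CompositeMap],
                      geom: GridGeometry, geographic: bool = False,
                      cell_size_km: float | None = None) -> pd.DataFrame:
    """Per-functional-class area change and gain/loss decomposition.

    For each class and scenario: area, % change vs baseline, and the cell
    counts gained / lost / stable, satisfying
    ``cells_scenario = cells_stable + cells_gained`` exactly.
    """
    rows = []
    base_bin = {fc: baseline.class_binary(fc) for fc in FUNCTIONAL_CLASSES}
    for sc, comp in scenarios.items():
        if comp.composite.shape != baseline.composite.shape:
            raise ValueError(f"{sc}: geometry mismatch with baseline")
        for fc in FUNCTIONAL_CLASSES:
            b = base_bin[fc] == 1.0
            s = comp.class_binary(fc) == 1.0
            gained = int((s & ~b).sum())
            lost = int((b & ~s).sum())
            stable = int((s & b).sum())
            a_base = area_of(base_bin[fc], geom, geographic, cell_size_km)
            a_scen = area_of(comp.class_binary(fc), geom, geographic, cell_size_km)
            rows.append({
                "scenario": sc, "functional_class": fc,
                "baseline_area_1e4km2": a_base, "area_1e4km2": a_scen,
                "change_pct": (100.0 * (a_scen - a_base) / a_base
                               if a_base > 0 else np.nan),
                "cells_gained": gained, "cells_lost": lost, "cells_stable": stable,
            })
    return pd.DataFrame(rows)
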