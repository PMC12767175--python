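"""Iterative per-species predictor screening.

Two stages, mirroring standard SDM practice: (1) fit a preliminary model on
all variables and drop those with zero contribution; (2) among the survivors,
resolve correlated pairs (|r| >= threshold, visited in descending |r|) by
keeping the higher-contribution member; then refit on the retained set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .maxent import MaxentModel, MaxentResults, permutation_contributions
from .features import build_features, select_feature_classes
from .occurrences import OccurrenceSet
from .rasters import EnvStack, correlation_matrix

__all__ = ["ScreeningResult", "ScreeningError", "screen_variables"]

log = logging.getLogger(__name__)


class ScreeningError(RuntimeError):
    """Screening removed every variable."""


@dataclass
class ScreeningResult:
    retained: list[str]
    dropped: list[tuple[str, str]]          # (variable, reason)
    contributions: pd.Series                # final, on the retained set
    preliminary_contributions: pd.Series
    final_results: MaxentResults | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = [{"variable": v, "status": "retained", "reason": "",
                 "contribution": float(self.contributions[v])} for v in self.retained]
        rows += [{"variable": v, "status": "dropped", "reason": r,
                  "contribution": 0.0} for v, r in self.dropped]
        return pd.DataFrame(rows).sort_values("variable").reset_index(drop=True)


def screen_variables(occ: OccurrenceSet, stack: EnvStack, threshold: float = 0.8,
                     reg_multiplier: float = 2.0, seed: int = 0,
                     kinds: set[str] | None = None, n_hinge_knots: int = 20,
                     corr_sample_size: int = 10_000) -> ScreeningResult:
    """Select the predictor subset for one species.

    Correlations are computed over background cells.  Pair visitation order is
    descending |r| with lexicographic tie-breaks; within a pair the
    lower-contribution member is dropped (contribution ties drop the
    lexicographically later name).
    """
    names = stack.layer_names
    if len(names) < 2:
        raise ValueError("need at least 2 variables to screen")
    rng = np.random.default_rng(seed)
    prelim_seed = int(rng.integers(2**31))
    corr_seed = int(rng.integers(2**31))

    geom = stack.geometry
    rows, cols = geom.cell_index(occ.records["lon"].to_numpy(),
                                 occ.records["lat"].to_numpy())
    ok = (rows >= 0) & stack.valid[np.clip(rows, 0, None), np.clip(cols, 0, None)]
    rows, cols = rows[ok], cols[ok]
    if kinds is None:
        kinds = select_feature_classes(rows.size)

    def _fit(sub: EnvStack):
        bg_raw = sub.table()
        fs = build_features(bg_raw, sub.layer_names, kinds, n_hinge_knots)
        pres_raw = sub.values_at(rows, cols)
        res = MaxentModel(fs.transform(pres_raw), fs.transform(bg_raw),
                          fs, reg_multiplier).fit()
        return res, pres_raw, bg_raw

    res, pres_raw, bg_raw = _fit(stack)
    prelim = permutation_contributions(res, pres_raw, bg_raw, seed=prelim_seed)

    dropped: list[tuple[str, str]] = []
    retained = [v for v in names if prelim[v] > 0.0]
    for v in names:
        if prelim[v] == 0.0:
            dropped.append((v, "zero_contribution"))
    if not retained:
        raise ScreeningError(f"{occ.species_id}: all variables dropped")

    if len(retained) > 1:
        r = correlation_matrix(stack, corr_sample_size, corr_seed, names=retained)
        pairs = []
        for i in range(len(retained)):
            for j in range(i + 1, len(retained)):
                if abs(r[i, j]) >= threshold:
                    pairs.append((abs(r[i, j]), retained[i], retained[j]))
        # descending |r|; ties resolved by lexicographic pair order
        pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
        alive = set(retained)
        for _, a, b in pairs:
            if a in alive and b in alive:
                if prelim[a] > prelim[b]:
                    loser, keeper = b, a
                elif prelim[a] < prelim[b]:
                    loser, keeper = a, b
                else:
                    keeper, loser = sorted((a, b))
                alive.discard(loser)
                dropped.append((loser, f"correlated_with:{keeper}"))
        retained = [v for v in retained if v in alive]

    if set(retained) == set(names):
        final_res, fp, fb = res, pres_raw, bg_raw
    else:
        final_res, fp, fb = _fit(stack.subset(retained))
    final = permutation_contributions(final_res, fp, fb,
                                      seed=int(rng.integers(2**31)))
    log.info("%s: retained %d/%d variables", occ.species_id, len(retained), len(names))
    return ScreeningResult(retained, dropped, final, prelim, final_res)
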