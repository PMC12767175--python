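"""MaxEnt feature expansion: linear, product, and hinge features scaled to [0, 1].

Scaling constants (per-layer min/max and hinge knots) are derived from the
*background* sample and frozen into the :class:`FeatureSet`, so presence points
and projection stacks are transformed with the same constants.  Values outside
the background range are clamped to [0, 1], matching standard MaxEnt projection
behaviour.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["Feature", "FeatureSet", "select_feature_classes", "build_features"]

#: presence-count thresholds for automatic feature-class selection
AUTO_HINGE_MIN = 15
AUTO_PRODUCT_MIN = 80


def select_feature_classes(n_presence: int) -> set[str]:
    """Feature kinds enabled for a given presence sample size.

    Fewer than 15 presences: linear only; 15-79: linear + hinge; 80 or more:
    linear + hinge + product.
    """
    if n_presence < 1:
        raise ValueError("n_presence must be >= 1")
    if n_presence < AUTO_HINGE_MIN:
        return {"linear"}
    if n_presence < AUTO_PRODUCT_MIN:
        return {"linear", "hinge"}
    return {"linear", "hinge", "product"}


@dataclass(frozen=True)
class Feature:
    kind: str                 # linear | product | hinge
    layers: tuple[str, ...]   # one layer (linear/hinge) or two (product)
    knot: float = np.nan      # hinge only, on the raw layer scale
    direction: str = ""       # hinge only: forward | reverse

    @property
    def name(self) -> str:
        if self.kind == "linear":
            return self.layers[0]
        if self.kind == "product":
            return f"{self.layers[0]}*{self.layers[1]}"
        return f"{self.direction[0]}h({self.layers[0]}@{self.knot:.6g})"


class FeatureSet:
    """Frozen feature definitions + background scaling for one model."""

    def __init__(self, layer_names: list[str], defs: list[Feature],
                 mins: dict[str, float], maxs: dict[str, float]):
        self.layer_names = list(layer_names)
        self.defs = list(defs)
        self.mins = dict(mins)
        self.maxs = dict(maxs)
        self._col = {n: i for i, n in enumerate(self.layer_names)}

    def __len__(self) -> int:
        return len(self.defs)

    @property
    def names(self) -> list[str]:
        return [f.name for f in self.defs]

    def kind_of(self, j: int) -> str:
        return self.defs[j].kind

    def variables_of(self, j: int) -> tuple[str, ...]:
        return self.defs[j].layers

    def _scaled(self, X: np.ndarray, layer: str) -> np.ndarray:
        lo, hi = self.mins[layer], self.maxs[layer]
        x = X[:, self._col[layer]]
        if hi == lo:
            return np.zeros_like(x)
        return np.clip((x - lo) / (hi - lo), 0.0, 1.0)

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Raw layer table (n, n_layers; columns in ``layer_names`` order) ->
        feature matrix (n, n_features) in [0, 1]."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != len(self.layer_names):
            raise ValueError(
                f"expected table with {len(self.layer_names)} columns "
                f"({self.layer_names}), got shape {X.shape}")
        cols = []
        for f in self.defs:
            if f.kind == "linear":
                cols.append(self._scaled(X, f.layers[0]))
            elif f.kind == "product":
                cols.append(self._scaled(X, f.layers[0]) * self._scaled(X, f.layers[1]))
            elif f.kind == "hinge":
                layer = f.layers[0]
                x = X[:, self._col[layer]]
                lo, hi, k = self.mins[layer], self.maxs[layer], f.knot
                if f.direction == "forward":
                    v = np.clip((x - k) / (hi - k), 0.0, 1.0)
                else:
                    v = np.clip((k - x) / (k - lo), 0.0, 1.0)
                cols.append(v)
            else:  # pragma: no cover
                raise ValueError(f"unknown feature kind {f.kind!r}")
        return np.column_stack(cols)


def build_features(background: np.ndarray, layer_names: list[str],
                   kinds: set[str], n_hinge_knots: int = 20) -> FeatureSet:
    """Construct a :class:`FeatureSet` from the background layer table.

    * linear: each layer min-max scaled to [0, 1];
    * product: all pairwise products of scaled layers;
    * hinge: forward and reverse hinges at ``n_hinge_knots`` equally spaced
      quantile knots strictly inside each layer's background range, each
      rescaled to [0, 1].

    A constant layer contributes its (zero-valued) linear feature only, with a
    warning.
    """
    if n_hinge_knots < 1:
        raise ValueError("n_hinge_knots must be >= 1")
    bad = kinds - {"linear", "product", "hinge"}
    if bad:
        raise ValueError(f"unknown feature kinds {sorted(bad)}")
    background = np.asarray(background, dtype=float)
    if background.ndim != 2 or background.shape[1] != len(layer_names):
        raise ValueError("background table does not match layer_names")
    mins = {n: float(np.nanmin(background[:, i])) for i, n in enumerate(layer_names)}
    maxs = {n: float(np.nanmax(background[:, i])) for i, n in enumerate(layer_names)}
    constant = [n for n in layer_names if mins[n] == maxs[n]]
    if constant:
        warnings.warn(f"constant layers {constant}: linear feature only")

    defs: list[Feature] = [Feature("linear", (n,)) for n in layer_names]
    if "product" in kinds:
        usable = [n for n in layer_names if n not in constant]
        for i, a in enumerate(usable):
            for b in usable[i + 1:]:
                defs.append(Feature("product", (a, b)))
    if "hinge" in kinds:
        qs = np.arange(1, n_hinge_knots + 1) / (n_hinge_knots + 1)
        for i, n in enumerate(layer_names):
            if n in constant:
                continue
            knots = np.unique(np.quantile(background[:, i], qs))
            knots = knots[(knots > mins[n]) & (knots < maxs[n])]
            for k in knots:
                defs.append(Feature("hinge", (n,), knot=float(k), direction="forward"))
                defs.append(Feature("hinge", (n,), knot=float(k), direction="reverse"))
    return FeatureSet(layer_names, defs, mins, maxs)
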