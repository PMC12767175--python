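"""Presence-background maximum-entropy species distribution model.

The model is the Gibbs distribution pi(x) = exp(lambda . f(x)) / Z over
background cells that minimizes the lasso-penalized log loss

    J(lambda) = -(1/m) sum_presences lambda . f(x_i) + log Z(lambda)
                + sum_j beta_j |lambda_j|

with per-feature penalties beta_j = reg_multiplier * beta0(kind, m) * s_j / sqrt(m),
where s_j is the presence-sample standard deviation of feature j and beta0 the
standard MaxEnt default schedule.  Fitting is cyclic coordinate descent with
soft-thresholding (Newton coordinate steps, backtracked so the convex objective
never increases).

API follows the statsmodels pattern: :class:`MaxentModel` holds the data and
settings; :meth:`MaxentModel.fit` returns a :class:`MaxentResults` carrying the
weights, normalizers, diagnostics and prediction methods.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .features import FeatureSet, build_features, select_feature_classes
from .occurrences import OccurrenceSet
from .rasters import EnvStack

__all__ = [
    "MaxentModel", "MaxentResults", "EvalReport", "CVResult",
    "ConvergenceError", "SpeciesSkipError",
    "auc", "default_betas", "permutation_contributions", "cv_replicates",
]

log = logging.getLogger(__name__)

#: beta0 interpolation table for linear (and product) features vs presence count
_LINEAR_BETA_SAMPLES = np.array([10.0, 30.0, 100.0])
_LINEAR_BETA_VALUES = np.array([1.0, 0.2, 0.05])
_HINGE_BETA0 = 0.5


class ConvergenceError(RuntimeError):
    """Coordinate descent failed to converge; carries the objective trace."""

    def __init__(self, message: str, trace: np.ndarray):
        super().__init__(message)
        self.trace = trace


class SpeciesSkipError(ValueError):
    """Too few presences to model this species; skip it."""


def _beta0(kind: str, m: int) -> float:
    if kind == "hinge":
        return _HINGE_BETA0
    return float(np.interp(m, _LINEAR_BETA_SAMPLES, _LINEAR_BETA_VALUES))


def default_betas(fs: FeatureSet, presence_F: np.ndarray, reg_multiplier: float) -> np.ndarray:
    """Per-feature lasso penalties from the MaxEnt default schedule."""
    m = presence_F.shape[0]
    sd = presence_F.std(axis=0, ddof=0)
    b0 = np.array([_beta0(fs.kind_of(j), m) for j in range(len(fs))])
    return reg_multiplier * b0 * sd / np.sqrt(m)


# ---------------------------------------------------------------------------
# coordinate descent core

def _cd_fit_py(F, pmean, betas, tol, max_passes):
    """Reference implementation (vectorized numpy inner steps)."""
    N, J = F.shape
    lam = np.zeros(J)
    eta = np.zeros(N)
    mx = 0.0
    w = np.ones(N)
    S = float(N)
    lin = 0.0
    l1 = 0.0
    obj = np.log(S)
    trace = np.empty(max_passes)
    converged = False
    n_pass = 0
    for p in range(max_passes):
        changed = False
        for j in range(J):
            fj = F[:, j]
            Ej = float(w @ fj) / S
            g = Ej - pmean[j]
            if lam[j] == 0.0 and abs(g) <= betas[j]:
                continue
            E2 = float(w @ (fj * fj)) / S
            h = max(E2 - Ej * Ej, 1e-12)
            z = lam[j] - g / h
            bh = betas[j] / h
            newl = np.sign(z) * max(abs(z) - bh, 0.0)
            d = newl - lam[j]
            if d == 0.0:
                continue
            accepted = False
            for _ in range(40):
                eta_try = eta + d * fj
                m2 = float(eta_try.max())
                s2 = float(np.exp(eta_try - m2).sum())
                new_obj = (-(lin + pmean[j] * d) + m2 + np.log(s2)
                           + l1 + betas[j] * (abs(lam[j] + d) - abs(lam[j])))
                if new_obj <= obj + 1e-12:
                    accepted = True
                    break
                d *= 0.5
                if abs(d) < 1e-15:
                    break
            if not accepted:
                continue
            eta = eta + d * fj
            lin += pmean[j] * d
            l1 += betas[j] * (abs(lam[j] + d) - abs(lam[j]))
            lam[j] += d
            mx = m2
            w = np.exp(eta - mx)
            S = s2
            obj = new_obj
            changed = True
        trace[p] = obj
        n_pass = p + 1
        if p > 0 and (trace[p - 1] - obj) <= tol * (abs(trace[p - 1]) + tol):
            converged = True
            break
        if not changed:
            converged = True
            break
    return lam, trace[:n_pass].copy(), converged


def _cd_fit_loops(F, pmean, betas, tol, max_passes):
    """Same algorithm with explicit loops, the numba-compiled hot path."""
    N, J = F.shape
    lam = np.zeros(J)
    eta = np.zeros(N)
    w = np.ones(N)
    S = float(N)
    lin = 0.0
    l1 = 0.0
    obj = np.log(S)
    trace = np.empty(max_passes)
    converged = False
    n_pass = 0
    for p in range(max_passes):
        changed = False
        for j in range(J):
            Ej = 0.0
            for i in range(N):
                Ej += w[i] * F[i, j]
            Ej /= S
            g = Ej - pmean[j]
            if lam[j] == 0.0 and abs(g) <= betas[j]:
                continue
            E2 = 0.0
            for i in range(N):
                E2 += w[i] * F[i, j] * F[i, j]
            E2 /= S
            h = E2 - Ej * Ej
            if h < 1e-12:
                h = 1e-12
            z = lam[j] - g / h
            bh = betas[j] / h
            if z > bh:
                newl = z - bh
            elif z < -bh:
                newl = z + bh
            else:
                newl = 0.0
            d = newl - lam[j]
            if d == 0.0:
                continue
            accepted = False
            m2 = 0.0
            s2 = 0.0
            new_obj = 0.0
            for _ in range(40):
                m2 = -1e300
                for i in range(N):
                    e = eta[i] + d * F[i, j]
                    if e > m2:
                        m2 = e
                s2 = 0.0
                for i in range(N):
                    s2 += np.exp(eta[i] + d * F[i, j] - m2)
                new_obj = (-(lin + pmean[j] * d) + m2 + np.log(s2)
                           + l1 + betas[j] * (abs(lam[j] + d) - abs(lam[j])))
                if new_obj <= obj + 1e-12:
                    accepted = True
                    break
                d *= 0.5
                if abs(d) < 1e-15:
                    break
            if not accepted:
                continue
            for i in range(N):
                eta[i] += d * F[i, j]
            lin += pmean[j] * d
            l1 += betas[j] * (abs(lam[j] + d) - abs(lam[j]))
            lam[j] += d
            for i in range(N):
                w[i] = np.exp(eta[i] - m2)
            S = s2
            obj = new_obj
            changed = True
        trace[p] = obj
        n_pass = p + 1
        if p > 0 and (trace[p - 1] - obj) <= tol * (abs(trace[p - 1]) + tol):
            converged = True
            break
        if not changed:
            converged = True
            break
    return lam, trace[:n_pass].copy(), converged


try:  # compiled hot path if numba is importable; semantics identical
    from numba import njit

    _cd_fit = njit(cache=True, fastmath=False)(_cd_fit_loops)
except Exception:  # pragma: no cover
    _cd_fit = _cd_fit_py


def maxent_objective(lam: np.ndarray, presence_F: np.ndarray,
                     background_F: np.ndarray, betas: np.ndarray) -> float:
    """The penalized log loss J(lambda) (used by fit diagnostics and tests)."""
    eta = background_F @ lam
    m = eta.max()
    logZ = m + np.log(np.exp(eta - m).sum())
    return float(-presence_F.mean(axis=0) @ lam + logZ + np.abs(lam) @ betas)


def auc(presence_scores, background_scores) -> float:
    """Mann-Whitney AUC of presence vs background scores (ties count 0.5)."""
    p = np.asarray(presence_scores, dtype=float)
    b = np.asarray(background_scores, dtype=float)
    if p.size == 0 or b.size == 0:
        raise ValueError("both score sets must be non-empty")
    y = np.concatenate([np.ones(p.size), np.zeros(b.size)])
    s = np.concatenate([p, b])
    if np.all(s == s[0]):
        return 0.5
    return float(roc_auc_score(y, s))


class MaxentModel:
    """Presence-background MaxEnt model, ready to fit.

    Parameters
    ----------
    presence_features, background_features
        Feature matrices in [0, 1], rows = presence points / background cells.
    feature_set
        The :class:`FeatureSet` that produced them (optional but required for
        raster prediction and contribution analysis).
    reg_multiplier
        Global inflation of the default lasso penalties (the study setting
        is 2).
    betas
        Explicit per-feature penalties, overriding the default schedule.
    """

    def __init__(self, presence_features: np.ndarray, background_features: np.ndarray,
                 feature_set: FeatureSet | None = None, reg_multiplier: float = 2.0,
                 betas: np.ndarray | None = None):
        P = np.asarray(presence_features, dtype=float)
        B = np.asarray(background_features, dtype=float)
        if P.ndim != 2 or B.ndim != 2 or P.shape[1] != B.shape[1]:
            raise ValueError("presence/background feature matrices are incompatible")
        if P.shape[0] < 2 or B.shape[0] < 2:
            raise ValueError("need >= 2 presences and >= 2 background cells")
        if np.nanmin(B) < -1e-9 or np.nanmax(B) > 1 + 1e-9:
            raise ValueError("features must be scaled to [0, 1]")
        self.presence_features = P
        self.background_features = np.ascontiguousarray(B)
        self.feature_set = feature_set
        self.reg_multiplier = float(reg_multiplier)
        if betas is not None:
            self.betas = np.asarray(betas, dtype=float)
            if self.betas.shape != (P.shape[1],):
                raise ValueError("betas length mismatch")
        elif feature_set is not None:
            self.betas = default_betas(feature_set, P, self.reg_multiplier)
        else:
            # no kind information: treat every feature as linear
            m = P.shape[0]
            self.betas = (self.reg_multiplier * _beta0("linear", m)
                          * P.std(axis=0) / np.sqrt(m))

    @classmethod
    def from_occurrences(cls, occ: OccurrenceSet, stack: EnvStack,
                         kinds: set[str] | None = None, n_hinge_knots: int = 20,
                         reg_multiplier: float = 2.0) -> "MaxentModel":
        """Build features from a stack's background cells and one species'
        (thinned) occurrences; presences on nodata cells are dropped."""
        rows, cols = stack.geometry.cell_index(occ.records["lon"].to_numpy(),
                                               occ.records["lat"].to_numpy())
        ok = (rows >= 0) & stack.valid[np.clip(rows, 0, None), np.clip(cols, 0, None)]
        rows, cols = rows[ok], cols[ok]
        if rows.size < 2:
            raise SpeciesSkipError(f"{occ.species_id}: fewer than 2 usable presences")
        if kinds is None:
            kinds = select_feature_classes(rows.size)
        fs = build_features(stack.table(), stack.layer_names, kinds, n_hinge_knots)
        P = fs.transform(stack.values_at(rows, cols))
        B = fs.transform(stack.table())
        return cls(P, B, fs, reg_multiplier)

    def fit(self, tol: float = 1e-7, maxiter: int = 5000) -> "MaxentResults":
        """Minimize the penalized log loss; raises :class:`ConvergenceError`
        if the relative objective improvement has not dropped below ``tol``
        within ``maxiter`` passes."""
        pmean = self.presence_features.mean(axis=0)
        lam, trace, converged = _cd_fit(self.background_features, pmean,
                                        self.betas, tol, maxiter)
        if not converged:
            raise ConvergenceError(
                f"maxent fit did not converge in {maxiter} passes "
                f"(last objective {trace[-1]:.8g})", trace)
        return MaxentResults(self, lam, trace)


class MaxentResults:
    """Fitted MaxEnt model: weights, normalizers, diagnostics, prediction."""

    def __init__(self, model: MaxentModel | None, lam: np.ndarray,
                 trace: np.ndarray | None = None, *,
                 feature_set: FeatureSet | None = None,
                 log_z: float | None = None, entropy: float | None = None,
                 reg_multiplier: float | None = None):
        self.model = model
        self.lam = np.asarray(lam, dtype=float)
        self.trace = trace
        self.feature_set = feature_set if feature_set is not None else (
            model.feature_set if model is not None else None)
        self.reg_multiplier = (reg_multiplier if reg_multiplier is not None
                               else (model.reg_multiplier if model else None))
        if model is not None:
            eta = model.background_features @ self.lam
            mx = eta.max()
            w = np.exp(eta - mx)
            S = w.sum()
            self.log_z = float(mx + np.log(S))
            pi = w / S
            self.raw_background = pi
            with np.errstate(divide="ignore", invalid="ignore"):
                plogp = np.where(pi > 0, pi * np.log(pi), 0.0)
            self.entropy = float(-plogp.sum())
        else:
            if log_z is None or entropy is None:
                raise ValueError("need log_z and entropy when no model is attached")
            self.log_z = float(log_z)
            self.entropy = float(entropy)
            self.raw_background = None

    # -- parameters -----------------------------------------------------
    @property
    def params(self) -> pd.Series:
        names = (self.feature_set.names if self.feature_set is not None
                 else [f"f{j}" for j in range(self.lam.size)])
        return pd.Series(self.lam, index=names, name="lambda")

    @property
    def n_nonzero(self) -> int:
        return int(np.count_nonzero(self.lam))

    @property
    def objective(self) -> float:
        return float(self.trace[-1]) if self.trace is not None else np.nan

    def active_variables(self) -> set[str]:
        """Source layers touched by at least one nonzero weight."""
        if self.feature_set is None:
            raise ValueError("no feature set attached")
        out: set[str] = set()
        for j in np.flatnonzero(self.lam):
            out.update(self.feature_set.variables_of(int(j)))
        return out

    # -- prediction ------------------------------------------------------
    def predict_features(self, F: np.ndarray, transform: str = "cloglog") -> np.ndarray:
        """Suitability for rows of a feature matrix built with this model's
        feature set.  ``raw`` is the Gibbs density normalized over the
        training background; ``cloglog`` is 1 - exp(-e^H * raw), in (0, 1)."""
        F = np.asarray(F, dtype=float)
        if F.ndim != 2 or F.shape[1] != self.lam.size:
            raise ValueError("feature matrix does not match the fitted model")
        raw = np.exp(F @ self.lam - self.log_z)
        if transform == "raw":
            return raw
        if transform == "cloglog":
            return 1.0 - np.exp(-np.exp(self.entropy) * raw)
        raise ValueError(f"unknown transform {transform!r}")

    def predict_table(self, X_raw: np.ndarray, transform: str = "cloglog") -> np.ndarray:
        """Suitability for rows of a raw layer table (layer_names order)."""
        if self.feature_set is None:
            raise ValueError("no feature set attached")
        return self.predict_features(self.feature_set.transform(X_raw), transform)

    def predict_map(self, stack: EnvStack, transform: str = "cloglog") -> np.ndarray:
        """Suitability raster over a stack (NaN on nodata cells)."""
        if self.feature_set is None:
            raise ValueError("no feature set attached")
        out = np.full(stack.geometry.shape, np.nan)
        out[stack.valid] = self.predict_table(
            stack.table(self.feature_set.layer_names), transform)
        return out

    # -- diagnostics -----------------------------------------------------
    def auc_train(self) -> float:
        if self.model is None:
            raise ValueError("training data not attached")
        return auc(self.predict_features(self.model.presence_features, "raw"),
                   self.predict_features(self.model.background_features, "raw"))

    def summary(self) -> str:
        lines = ["Maxent presence-background model",
                 "=" * 48,
                 f"n presences:        {self.model.presence_features.shape[0] if self.model else 'n/a'}",
                 f"n background:       {self.model.background_features.shape[0] if self.model else 'n/a'}",
                 f"n features:         {self.lam.size} ({self.n_nonzero} nonzero)",
                 f"reg multiplier:     {self.reg_multiplier}",
                 f"log Z:              {self.log_z:.6f}",
                 f"entropy H:          {self.entropy:.6f}"]
        if self.trace is not None:
            lines.append(f"objective:          {self.objective:.6f} "
                         f"({len(self.trace)} passes)")
        if self.model is not None:
            lines.append(f"training AUC:       {self.auc_train():.4f}")
        lines.append("-" * 48)
        lines.append(f"{'feature':<30}{'lambda':>12}")
        p = self.params
        for name in p.index[np.flatnonzero(self.lam)]:
            lines.append(f"{name:<30}{p[name]:>12.5f}")
        return "\n".join(lines)

    # -- serialization ---------------------------------------------------
    def save(self, path) -> None:
        """Flat text lambdas file: per-layer scaling, per-feature weight,
        and a metadata block (Z, H, transform, multiplier)."""
        fs = self.feature_set
        if fs is None:
            raise ValueError("no feature set attached")
        with open(path, "w") as fh:
            fh.write("# grasscast maxent lambdas v1\n")
            for n in fs.layer_names:
                fh.write(f"layer\t{n}\t{float(fs.mins[n])!r}\t{float(fs.maxs[n])!r}\n")
            for f, l in zip(fs.defs, self.lam):
                fh.write(f"feature\t{f.kind}\t{','.join(f.layers)}\t"
                         f"{float(f.knot)!r}\t{f.direction}\t{float(l)!r}\n")
            fh.write(f"meta\tlog_z\t{float(self.log_z)!r}\n")
            fh.write(f"meta\tentropy\t{float(self.entropy)!r}\n")
            fh.write(f"meta\treg_multiplier\t{float(self.reg_multiplier)!r}\n")
            fh.write("meta\ttransform\tcloglog\n")

    @classmethod
    def load(cls, path) -> "MaxentResults":
        from .features import Feature
        layer_names, mins, maxs, defs, lams = [], {}, {}, [], []
        meta: dict[str, float] = {}
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                if parts[0] == "layer":
                    layer_names.append(parts[1])
                    mins[parts[1]] = float(parts[2])
                    maxs[parts[1]] = float(parts[3])
                elif parts[0] == "feature":
                    defs.append(Feature(parts[1], tuple(parts[2].split(",")),
                                        knot=float(parts[3]), direction=parts[4]))
                    lams.append(float(parts[5]))
                elif parts[0] == "meta" and parts[1] != "transform":
                    meta[parts[1]] = float(parts[2])
        fs = FeatureSet(layer_names, defs, mins, maxs)
        return cls(None, np.array(lams), feature_set=fs, log_z=meta["log_z"],
                   entropy=meta["entropy"],
                   reg_multiplier=meta.get("reg_multiplier"))


# ---------------------------------------------------------------------------
# variable contributions and cross-validation

def permutation_contributions(results: MaxentResults, presence_raw: np.ndarray,
                              background_raw: np.ndarray, seed: int,
                              n_permutations: int = 5) -> pd.Series:
    """Per-variable contribution (%) as permutation importance.

    For each source variable the training AUC drop is measured when that
    variable's raw values are permuted across all cells (presences and
    background jointly), averaged over ``n_permutations`` permutations,
    floored at 0 and normalized to sum to 100.  Variables whose features all
    have zero weight contribute exactly 0 without permutation.
    """
    fs = results.feature_set
    if fs is None:
        raise ValueError("no feature set attached")
    m = presence_raw.shape[0]
    combined = np.vstack([presence_raw, background_raw])
    base_auc = auc(results.predict_features(fs.transform(presence_raw), "raw"),
                   results.predict_features(fs.transform(background_raw), "raw"))
    active = results.active_variables()
    # permutation streams keyed by the variable's rank in sorted name order,
    # so results do not depend on the input column order
    name_rank = {n: i for i, n in enumerate(sorted(fs.layer_names))}
    drops = {}
    for vi, var in enumerate(fs.layer_names):
        if var not in active:
            drops[var] = 0.0
            continue
        rng = np.random.default_rng([seed, name_rank[var]])
        d = 0.0
        for _ in range(n_permutations):
            perm = combined.copy()
            perm[:, vi] = rng.permutation(perm[:, vi])
            F = fs.transform(perm)
            d += base_auc - auc(
                results.predict_features(F[:m], "raw"),
                results.predict_features(F[m:], "raw"))
        drops[var] = max(d / n_permutations, 0.0)
    contrib = pd.Series(drops, dtype=float)
    total = contrib.sum()
    if total > 0:
        contrib = 100.0 * contrib / total
    else:
        # no permutation changed the AUC: split evenly among active variables
        # (all variables if the model is uniform) so shares still total 100
        pool = sorted(active) if active else list(fs.layer_names)
        contrib[:] = 0.0
        contrib[pool] = 100.0 / len(pool)
    return contrib.reindex(fs.layer_names)


@dataclass
class EvalReport:
    """Replicate-level evaluation of one species' model."""

    replicates: pd.DataFrame           # replicate, n_train, n_test, auc_train, auc_test
    mean_test_auc: float
    contributions: pd.Series | None = None

    def summary(self) -> str:
        lines = [f"{'rep':>4}{'n_train':>9}{'n_test':>8}{'AUC_train':>11}{'AUC_test':>10}"]
        for _, r in self.replicates.iterrows():
            lines.append(f"{int(r.replicate):>4}{int(r.n_train):>9}{int(r.n_test):>8}"
                         f"{r.auc_train:>11.4f}{r.auc_test:>10.4f}")
        lines.append(f"mean test AUC: {self.mean_test_auc:.4f}")
        if self.contributions is not None:
            lines.append("variable contributions (%):")
            for v, c in self.contributions.sort_values(ascending=False).items():
                lines.append(f"  {v:<20}{c:8.2f}")
        return "\n".join(lines)


@dataclass
class CVResult:
    """Replicate cross-validation output for one species."""

    species_id: str
    mean_map: np.ndarray               # per-cell mean cloglog suitability
    report: EvalReport
    test_predictions: list[np.ndarray] = field(default_factory=list)
    background_predictions: np.ndarray | None = None
    feature_set: FeatureSet | None = None
    projected: dict[str, np.ndarray] = field(default_factory=dict)

    def pooled_test_predictions(self) -> np.ndarray:
        return np.concatenate(self.test_predictions)


def cv_replicates(occ: OccurrenceSet, stack: EnvStack,
                  kinds: set[str] | None = None, reg_multiplier: float = 2.0,
                  n_replicates: int = 10, train_frac: float = 0.75,
                  seed: int = 0, n_hinge_knots: int = 20,
                  min_presences: int = 8,
                  compute_contributions: bool = False,
                  project_stacks: dict[str, EnvStack] | None = None) -> CVResult:
    """Random-subsampling replicate cross-validation (default 75/25 x 10).

    Each replicate fits on a random ``train_frac`` share of the presences and
    is evaluated by AUC of the held-out presences against the full background.
    The final suitability map is the per-cell mean of the replicate cloglog
    maps; ``project_stacks`` (e.g. climate-scenario stacks sharing the
    training geometry) receive replicate-mean maps the same way.  Requires at
    least ``min_presences`` usable presence cells.
    """
    geom = stack.geometry
    rows, cols = geom.cell_index(occ.records["lon"].to_numpy(),
                                 occ.records["lat"].to_numpy())
    ok = (rows >= 0) & stack.valid[np.clip(rows, 0, None), np.clip(cols, 0, None)]
    rows, cols = rows[ok], cols[ok]
    m = rows.size
    if m < min_presences:
        raise SpeciesSkipError(
            f"{occ.species_id}: {m} usable presences < {min_presences}; skip this species")
    if kinds is None:
        kinds = select_feature_classes(m)
    bg_raw = stack.table()
    fs = build_features(bg_raw, stack.layer_names, kinds, n_hinge_knots)
    B = fs.transform(bg_raw)
    presence_raw = stack.values_at(rows, cols)
    P = fs.transform(presence_raw)

    n_train = int(np.floor(train_frac * m))
    n_train = max(2, min(n_train, m - 1))
    rng = np.random.default_rng(seed)
    maps = np.zeros(geom.shape)
    proj_tables = {}
    proj_sums = {}
    if project_stacks:
        for name, ps in project_stacks.items():
            if ps.geometry != geom:
                raise ValueError(f"projection stack {name!r} geometry mismatch")
            proj_tables[name] = ps.table(stack.layer_names)
            proj_sums[name] = np.zeros(geom.shape)
    rows_rep = []
    test_preds: list[np.ndarray] = []
    full_valid = stack.valid
    for rep in range(n_replicates):
        order = rng.permutation(m)
        tr, te = order[:n_train], order[n_train:]
        model = MaxentModel(P[tr], B, fs, reg_multiplier)
        res = model.fit()
        bg_scores = res.predict_features(B, "cloglog")
        tr_scores = res.predict_features(P[tr], "cloglog")
        te_scores = res.predict_features(P[te], "cloglog")
        rows_rep.append((rep, tr.size, te.size,
                         auc(tr_scores, bg_scores), auc(te_scores, bg_scores)))
        test_preds.append(te_scores)
        rep_map = np.full(geom.shape, np.nan)
        rep_map[full_valid] = bg_scores
        maps += np.where(full_valid, rep_map, 0.0)
        for name, tab in proj_tables.items():
            pm = np.zeros(geom.shape)
            pv = project_stacks[name].valid
            pm[pv] = res.predict_table(tab, "cloglog")
            proj_sums[name] += pm
    mean_map = np.where(full_valid, maps / n_replicates, np.nan)
    projected = {}
    for name, s in proj_sums.items():
        pv = project_stacks[name].valid
        projected[name] = np.where(pv, s / n_replicates, np.nan)
    rep_df = pd.DataFrame(rows_rep, columns=["replicate", "n_train", "n_test",
                                             "auc_train", "auc_test"])
    contributions = None
    if compute_contributions:
        full_res = MaxentModel(P, B, fs, reg_multiplier).fit()
        contributions = permutation_contributions(
            full_res, presence_raw, bg_raw, seed=int(rng.integers(2**31)))
    report = EvalReport(rep_df, float(rep_df["auc_test"].mean()), contributions)
    return CVResult(occ.species_id, mean_map, report, test_preds,
                    mean_map[full_valid], fs, projected)
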