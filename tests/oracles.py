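"""Independent oracles used by the test suite (kept apart from the package)."""

import numpy as np
from scipy.optimize import minimize


def maxent_oracle_objective(presence_F, background_F, betas):
    """Minimum of the penalized maxent log loss via a generic convex solver.

    Splits lambda = a - b with a, b >= 0 so the l1 term is smooth, and runs
    L-BFGS-B with the analytic gradient.  Fully independent of the
    coordinate-descent path.
    """
    P = np.asarray(presence_F, float)
    B = np.asarray(background_F, float)
    betas = np.asarray(betas, float)
    J = B.shape[1]
    pmean = P.mean(axis=0)

    def fg(ab):
        lam = ab[:J] - ab[J:]
        eta = B @ lam
        mx = eta.max()
        w = np.exp(eta - mx)
        S = w.sum()
        obj = -pmean @ lam + mx + np.log(S) + betas @ (ab[:J] + ab[J:])
        g = (w / S) @ B - pmean
        return obj, np.concatenate([g + betas, -g + betas])

    sol = minimize(fg, np.zeros(2 * J), jac=True, method="L-BFGS-B",
                   bounds=[(0, None)] * (2 * J),
                   options={"maxiter": 5000, "ftol": 1e-15, "gtol": 1e-12})
    return float(sol.fun)


def auc_by_pair_counting(presence_scores, background_scores):
    """Brute-force Mann-Whitney AUC: wins + half-ties over all pairs."""
    wins = ties = 0
    for p in presence_scores:
        for b in background_scores:
            if p > b:
                wins += 1
            elif p == b:
                ties += 1
    return (wins + 0.5 * ties) / (len(presence_scores) * len(background_scores))


def max_sss_by_scan(presence_pred, background_pred):
    """Exhaustive maxSSS scan over every unique candidate threshold."""
    p = np.asarray(presence_pred, float)
    b = np.asarray(background_pred, float)
    best_t, best_s = None, -np.inf
    for t in np.unique(np.concatenate([p, b])):
        s = (p >= t).mean() + (b < t).mean()
        if s > best_s + 1e-12:
            best_s, best_t = s, t
    return float(best_t), float(best_s)
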