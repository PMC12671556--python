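"""Small dense weighted logistic regression via IRLS.

The replicated simulation harness needs thousands of little spline
logistic fits per cohort (degree cross-validation times folds times
models), so the solver is a tight numpy/BLAS loop with a ridge jitter
for separation and a linear-predictor clamp.  Accuracy against
statsmodels GLM is covered by the test suite.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import LinAlgError, cho_factor, cho_solve
from scipy.special import expit

_LP_CLAMP = 30.0


def fit_logistic_irls(Xd: np.ndarray, y: np.ndarray,
                      sample_weight: np.ndarray | None = None,
                      ridge: float = 1e-8, max_iter: int = 60,
                      tol: float = 1e-7, beta0: np.ndarray | None = None) -> np.ndarray:
    """Weighted logistic MLE (tiny ridge for numerical definiteness).

    Under complete separation the linear predictor is clamped and the
    loop exits at ``max_iter``; downstream probability truncation makes
    the fitted values usable regardless.
    """
    n, d = Xd.shape
    beta = np.zeros(d) if beta0 is None else beta0.copy()
    w_obs = None if sample_weight is None else sample_weight
    eye = ridge * n * np.eye(d)
    for _ in range(max_iter):
        lp = np.clip(Xd @ beta, -_LP_CLAMP, _LP_CLAMP)
        p = expit(lp)
        resid = (p - y) if w_obs is None else w_obs * (p - y)
        g = Xd.T @ resid
        wirls = p * (1.0 - p) + 1e-12
        if w_obs is not None:
            wirls = wirls * w_obs
        H = (Xd * wirls[:, None]).T @ Xd + eye
        try:
            step = cho_solve(cho_factor(H, check_finite=False), g,
                             check_finite=False)
        except LinAlgError:
            step = np.linalg.lstsq(H, g, rcond=None)[0]
        beta -= step
        if np.abs(step).max() < tol:
            break
    return beta


def predict_proba(Xd: np.ndarray, beta: np.ndarray) -> np.ndarray:
    return expit(np.clip(Xd @ beta, -_LP_CLAMP, _LP_CLAMP))


def mean_nll(p: np.ndarray, y: np.ndarray) -> float:
    """Mean Bernoulli negative log-likelihood (out-of-fold entropy)."""
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log1p(-p)))


def cv_entropy(Xd: np.ndarray, y: np.ndarray, n_folds: int,
               rng: np.random.Generator, ridge: float = 1e-8,
               max_iter: int = 20, tol: float = 1e-6) -> float:
    """Mean out-of-fold entropy of a logistic fit under a random K-fold
    split of the rows (the degree-selection criterion).

    All fold fits run through one batched IRLS loop (per-fold 0/1
    training weights), warm-started at the full-data solution.
    """
    n, d = Xd.shape
    fold = np.empty(n, dtype=int)
    fold[rng.permutation(n)] = np.arange(n) % n_folds
    Wtr = (fold[:, None] != np.arange(n_folds)).astype(float)  # (n, F)
    beta_full = fit_logistic_irls(Xd, y, ridge=ridge)
    B = np.repeat(beta_full[:, None], n_folds, axis=1)  # (d, F)
    XdT = Xd.T
    eye = ridge * n * np.eye(d)
    active = np.ones(n_folds, dtype=bool)
    for _ in range(max_iter):
        LP = np.clip(Xd @ B, -_LP_CLAMP, _LP_CLAMP)
        P = expit(LP)
        G = XdT @ ((P - y[:, None]) * Wtr)
        worst = 0.0
        for f in range(n_folds):
            if not active[f]:
                continue
            wirls = Wtr[:, f] * (P[:, f] * (1.0 - P[:, f]) + 1e-12)
            H = (Xd * wirls[:, None]).T @ Xd + eye
            try:
                step = cho_solve(cho_factor(H, check_finite=False), G[:, f],
                                 check_finite=False)
            except LinAlgError:
                step = np.linalg.lstsq(H, G[:, f], rcond=None)[0]
            B[:, f] -= step
            ms = np.abs(step).max()
            if ms < tol:
                active[f] = False
            worst = max(worst, ms)
        if worst < tol:
            break
    LP = np.clip(Xd @ B, -_LP_CLAMP, _LP_CLAMP)
    P = expit(LP)
    tot = 0.0
    for f in range(n_folds):
        te = fold == f
        tot += mean_nll(P[te, f], y[te])
    return tot / n_folds
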