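"""ATE estimators: semi-supervised (surrogate-assisted), supervised,
unsupervised, ensemble and crude.

The semi-supervised estimator averages the estimated efficient
influence values

    V_i = mu1(X) + Pi1(W)/pi1(X) * (m1(W) - mu1(X))
        - mu0(X) - Pi0(W)/pi0(X) * (m0(W) - mu0(X))
        + R/rho * [ A(Y - mu1(X))/pi1(X) - (1-A)(Y - mu0(X))/pi0(X)
                    - Pi1(m1 - mu1)/pi1 + Pi0(m0 - mu0)/pi0 ]

over all N subjects.  The first line is the surrogate-imputed plug-in
available for everyone; the labeled-only bracket debiases it.  The
variance of sqrt(n)(Delta_hat - Delta*) is estimated by rho_hat times
the empirical variance of V_i over all N subjects, which captures the
uncertainty of both the labeled and the (large but finite) unlabeled
set.  With every subject labeled and rho = 1 the imputation terms
cancel exactly and the estimator reduces to the cross-fitted AIPW.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import norm

from .datasets import ATEEstimate, NuisancePredictions, ObservedDataset

__all__ = [
    "phi_cmp",
    "influence_values",
    "smmal_estimate",
    "aipw_complete",
    "supervised_estimate",
    "unsupervised_estimate",
    "ensemble_estimate",
    "crude_estimates",
    "dichotomize",
]


def phi_cmp(y, a, pi1, pi0, mu1, mu0, delta):
    """Complete-data efficient influence value (AIPW summand, centered).

    mu(1,x) - mu(0,x) + 1{a=1}(y - mu(1,x))/pi(1,x)
                      - 1{a=0}(y - mu(0,x))/pi(0,x) - delta
    """
    a = np.asarray(a, dtype=float)
    return (mu1 - mu0
            + np.where(a == 1, (y - mu1) / pi1, 0.0)
            - np.where(a == 0, (y - mu0) / pi0, 0.0)
            - delta)


def influence_values(dataset: ObservedDataset, preds: NuisancePredictions,
                     rho: float | None = None) -> np.ndarray:
    """Per-subject estimated influence values (uncentered: their mean is
    the point estimate).  Masked A/Y are never evaluated: the labeled
    bracket is computed on labeled rows only."""
    if rho is None:
        rho = dataset.rho_hat
    if not 0 < rho <= 1:
        raise ValueError("rho must lie in (0, 1]")
    p = preds
    base = (p.mu1 + p.Pi1 / p.pi1 * (p.m1 - p.mu1)
            - p.mu0 - p.Pi0 / p.pi0 * (p.m0 - p.mu0))
    V = base.copy()
    lab = dataset.labeled
    A = dataset.A[lab]
    Y = dataset.Y[lab]
    if np.isnan(A).any() or np.isnan(Y).any():
        raise ValueError("labeled subject with missing A or Y")
    pi1, pi0 = p.pi1[lab], p.pi0[lab]
    mu1, mu0 = p.mu1[lab], p.mu0[lab]
    Pi1, Pi0 = p.Pi1[lab], p.Pi0[lab]
    m1, m0 = p.m1[lab], p.m0[lab]
    V[lab] += (
        (A * Y - A * mu1) / (rho * pi1)
        - ((1 - A) * Y - (1 - A) * mu0) / (rho * pi0)
        - (Pi1 * m1 - Pi1 * mu1) / (rho * pi1)
        + (Pi0 * m0 - Pi0 * mu0) / (rho * pi0)
    )
    return V


def _wrap(delta: float, infl: np.ndarray, rho: float, n: int, N: int,
          level_alpha: float, method: str, meta=None) -> ATEEstimate:
    V = float(rho / N * np.sum((infl - delta) ** 2))
    z = norm.ppf(1 - level_alpha / 2)
    half = z * np.sqrt(V / n)
    return ATEEstimate(
        delta=float(delta), influence=infl, V=V, n=n, N=N, rho_hat=rho,
        ci_low=float(delta - half), ci_high=float(delta + half),
        level=1 - level_alpha, method=method, meta=meta or {},
    )


def smmal_estimate(dataset: ObservedDataset, preds: NuisancePredictions,
                   alpha_level: float = 0.05, rho: float | None = None,
                   method: str = "smmal") -> ATEEstimate:
    """Semi-supervised ATE estimate with influence-based variance and
    normal-quantile confidence interval."""
    n = dataset.n_labeled
    if n == 0:
        raise ValueError("no labeled subjects")
    rho = dataset.rho_hat if rho is None else rho
    infl = influence_values(dataset, preds, rho)
    return _wrap(infl.mean(), infl, rho, n, dataset.N, alpha_level, method,
                 meta=dict(preds.meta))


def aipw_complete(A: np.ndarray, Y: np.ndarray, pi1: np.ndarray,
                  pi0: np.ndarray, mu1: np.ndarray, mu0: np.ndarray,
                  alpha_level: float = 0.05, method: str = "aipw") -> ATEEstimate:
    """Cross-fitted AIPW on fully observed (A, Y): the rho = 1 limit."""
    N = len(A)
    v = (mu1 - mu0
         + np.where(A == 1, (Y - mu1) / pi1, 0.0)
         - np.where(A == 0, (Y - mu0) / pi0, 0.0))
    return _wrap(v.mean(), v, 1.0, N, N, alpha_level, method)


def supervised_estimate(dataset: ObservedDataset, preds: NuisancePredictions,
                        alpha_level: float = 0.05,
                        method: str = "sl_dml") -> ATEEstimate:
    """Labeled-only cross-fitted DML (AIPW) benchmark.

    Uses only the confounder models pi-hat, mu-hat; equals the labeled-
    subset AIPW mean because (1/N)(1/rho_hat) = 1/n.
    """
    n = dataset.n_labeled
    rho = dataset.rho_hat
    lab = dataset.labeled
    A, Y = dataset.A[lab], dataset.Y[lab]
    psi = (preds.mu1[lab] - preds.mu0[lab]
           + np.where(A == 1, (Y - preds.mu1[lab]) / preds.pi1[lab], 0.0)
           - np.where(A == 0, (Y - preds.mu0[lab]) / preds.pi0[lab], 0.0))
    infl = np.zeros(dataset.N)
    infl[lab] = psi / rho
    return _wrap(infl.mean(), infl, rho, n, dataset.N, alpha_level, method)


def dichotomize(S: np.ndarray, prevalence: float) -> np.ndarray:
    """Threshold a surrogate score at the sample quantile matching the
    labeled-set prevalence: the round(N*prev) largest scores become 1."""
    N = len(S)
    k = int(round(N * prevalence))
    k = min(max(k, 1), N - 1)
    thr = np.partition(S, N - k)[N - k]
    return (S >= thr).astype(float)


def unsupervised_estimate(dataset: ObservedDataset, alpha_level: float = 0.05,
                          K: int = 10, M: float = 2.2, seed: int = 0,
                          max_degree: int | None = 22) -> ATEEstimate:
    """UL benchmark: dichotomized surrogates treated as the true (A, Y),
    then complete-data cross-fitted AIPW with spline nuisances on X."""
    from .crossfit import assign_folds
    from .splines import fit_spline_nuisances

    lab = dataset.labeled
    for j in range(dataset.q):
        if np.ptp(dataset.S[:, j]) == 0:
            raise ValueError("degenerate (constant) surrogate")
    prev_A = float(np.nanmean(dataset.A[lab]))
    prev_Y = float(np.nanmean(dataset.Y[lab]))
    A_t = dichotomize(dataset.S[:, 0], prev_A)
    Y_t = dichotomize(dataset.S[:, 1], prev_Y)
    folds = assign_folds(dataset.N, K, seed)
    preds = fit_spline_nuisances(
        dataset.X[:, 1:], None, A_t, Y_t, np.ones(dataset.N, dtype=bool),
        folds, M=M, max_degree=max_degree, seed=seed, with_imputation=False,
    )
    est = aipw_complete(A_t, Y_t, preds.pi1, preds.pi0, preds.mu1, preds.mu0,
                        alpha_level, method="ul")
    est.meta.update({"prev_A": prev_A, "prev_Y": prev_Y})
    return est


def ensemble_estimate(ssl: ATEEstimate, sl: ATEEstimate,
                      alpha_level: float = 0.05) -> ATEEstimate:
    """Optimal linear combination of the semi-supervised and supervised
    estimators from their estimated influence vectors."""
    if ssl.N != sl.N:
        raise ValueError("estimates must share the cohort")
    ci = ssl.influence - ssl.delta
    cj = sl.influence - sl.delta
    v_ssl = float(np.mean(ci**2))
    v_sl = float(np.mean(cj**2))
    cov = float(np.mean(ci * cj))
    den = v_ssl + v_sl - 2 * cov
    fallback = den <= max(1e-12 * max(v_ssl, v_sl), 0.0)
    b = 0.0 if fallback else (v_ssl - cov) / den
    delta = ssl.delta + b * (sl.delta - ssl.delta)
    infl = (1 - b) * ssl.influence + b * sl.influence
    est = _wrap(delta, infl, ssl.rho_hat, ssl.n, ssl.N, alpha_level, "ensemble")
    est.meta.update({"b_hat": b, "fallback": fallback})
    return est


def crude_estimates(dataset: ObservedDataset, alpha_level: float = 0.05) -> dict:
    """Unadjusted comparators: labeled-set arm-mean difference (SL crude)
    and dichotomized-surrogate arm-mean difference over all N (UL crude)."""
    lab = dataset.labeled
    A, Y = dataset.A[lab], dataset.Y[lab]
    out = {}
    d_sl = Y[A == 1].mean() - Y[A == 0].mean()
    v_sl = Y[A == 1].var(ddof=1) / (A == 1).sum() + Y[A == 0].var(ddof=1) / (A == 0).sum()
    z = norm.ppf(1 - alpha_level / 2)
    out["sl_crude"] = {"delta": float(d_sl),
                       "ci": [float(d_sl - z * np.sqrt(v_sl)),
                              float(d_sl + z * np.sqrt(v_sl))]}
    A_t = dichotomize(dataset.S[:, 0], float(A.mean()))
    Y_t = dichotomize(dataset.S[:, 1], float(Y.mean()))
    d_ul = Y_t[A_t == 1].mean() - Y_t[A_t == 0].mean()
    v_ul = (Y_t[A_t == 1].var(ddof=1) / (A_t == 1).sum()
            + Y_t[A_t == 0].var(ddof=1) / (A_t == 0).sum())
    out["ul_crude"] = {"delta": float(d_ul),
                       "ci": [float(d_ul - z * np.sqrt(v_ul)),
                              float(d_ul + z * np.sqrt(v_ul))]}
    return out
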