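"""Tensor-product B-spline logistic regression for the low-dimensional
nuisance models.

The propensity score pi(1, x) and outcome regressions mu(a, x) are fit
on the confounders alone; the imputation models Pi(1, w) and m(a, w)
are fit on the stacked confounder+surrogate vector W.  All fits use
first-order (piecewise-linear) B-spline bases with equally spaced
interior knots on the training range, logistic link, and a
cross-validated number of degrees of freedom.  Fitted probabilities
are truncated into [g(-M), g(M)] (g the logistic link), the bounded-
estimator contract that keeps inverse-probability weights stable.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import BSpline
from scipy.special import expit

from ._glm import cv_entropy, fit_logistic_irls, mean_nll, predict_proba
from .crossfit import FoldAssignment
from .datasets import NuisancePredictions, ObservedDataset

__all__ = [
    "bspline_basis",
    "select_degree_cv",
    "fit_all_nuisances_lowd",
    "fit_spline_nuisances",
]


def _knots(lo: float, hi: float, degree: int, order: int) -> np.ndarray:
    """Open knot vector with degree-1 equally spaced interior knots,
    giving degree+order basis functions."""
    if hi <= lo:
        hi = lo + 1e-9
    interior = np.linspace(lo, hi, degree + 1)[1:-1]
    return np.concatenate([np.full(order + 1, lo), interior, np.full(order + 1, hi)])


def _basis_1d(x: np.ndarray, lo: float, hi: float, degree: int, order: int) -> np.ndarray:
    t = _knots(lo, hi, degree, order)
    xc = np.clip(x, lo, hi)  # clamp extrapolation to the boundary knots
    return BSpline.design_matrix(xc, t, order).toarray()


def bspline_basis(values: np.ndarray, degrees, order: int = 1,
                  ranges=None) -> np.ndarray:
    """Tensor-product B-spline design matrix.

    Parameters
    ----------
    values : (n,) or (n, D) array of covariates.
    degrees : int or length-D sequence; each dimension contributes
        ``degree + order`` basis functions, the tensor basis has the
        product dimension.
    ranges : optional list of (lo, hi) per dimension (training range);
        defaults to the min/max of ``values``.  Out-of-range inputs are
        clamped.
    """
    V = np.asarray(values, dtype=float)
    if not np.isfinite(V).all():
        raise ValueError("non-finite covariate values")
    if V.ndim == 1:
        V = V[:, None]
    D = V.shape[1]
    degrees = [int(degrees)] * D if np.isscalar(degrees) else [int(d) for d in degrees]
    if len(degrees) != D:
        raise ValueError("one degree per covariate dimension required")
    if ranges is None:
        ranges = [(V[:, j].min(), V[:, j].max()) for j in range(D)]
    B = _basis_1d(V[:, 0], *ranges[0], degrees[0], order)
    for j in range(1, D):
        Bj = _basis_1d(V[:, j], *ranges[j], degrees[j], order)
        # row-wise Khatri-Rao product
        B = (B[:, :, None] * Bj[:, None, :]).reshape(len(V), -1)
    return B


def max_degree_default(n_rows: int, ndim: int, order: int = 1) -> int:
    """Largest candidate degree: 1-D follows the floor(sqrt(n)) rule;
    tensor bases are capped so the basis dimension stays <= n/4."""
    if ndim == 1:
        return max(1, int(np.floor(np.sqrt(n_rows))))
    d = 1
    while (d + 1 + order) ** ndim <= max(n_rows // 4, (1 + order) ** ndim):
        d += 1
    return d


def select_degree_cv(features: np.ndarray, y: np.ndarray,
                     max_degree: int | None = None, order: int = 1,
                     n_folds: int = 10, seed: int = 0) -> int:
    """Degree minimizing the mean out-of-fold entropy; ties go to the
    smaller (simpler) degree."""
    V = np.asarray(features, dtype=float)
    if V.ndim == 1:
        V = V[:, None]
    n, D = V.shape
    cap = max_degree_default(n, D, order)
    if max_degree is None:
        max_degree = cap
    elif D > 1:
        # the basis-dimension cap binds for tensor bases no matter what
        # candidate ceiling the caller asks for
        max_degree = min(max_degree, cap)
    rng = np.random.default_rng(seed)
    best_deg, best_ent = None, np.inf
    failures = []
    for deg in range(1, max_degree + 1):
        try:
            B = bspline_basis(V, deg, order=order)
            ent = cv_entropy(B, y, n_folds, np.random.default_rng(rng.integers(2**31)))
        except Exception:
            failures.append(deg)
            continue
        if ent < best_ent - 1e-12:
            best_ent, best_deg = ent, deg
    if best_deg is None:
        raise RuntimeError(
            f"all candidate spline fits failed (smallest failing degree {failures[0]})"
        )
    return best_deg


def fit_spline_nuisances(X_raw: np.ndarray, S_raw: np.ndarray | None,
                         A: np.ndarray, Y: np.ndarray, labeled: np.ndarray,
                         folds: FoldAssignment, M: float = 2.2,
                         order: int = 1, max_degree: int | None = None,
                         seed: int = 0, with_imputation: bool = True,
                         degrees: dict | None = None) -> NuisancePredictions:
    """Cross-fitted spline-logistic nuisance predictions.

    ``A``/``Y`` may contain NaN off the labeled rows; only labeled rows
    ever enter a training set.  Degree selection is run once per model
    on its full training subset; coefficients are then re-fit per fold
    on the out-of-fold rows and each subject is predicted from the fit
    that excluded their fold.  Pass ``degrees`` (dict model -> int) to
    bypass selection.
    """
    X_raw = np.atleast_2d(np.asarray(X_raw, dtype=float))
    if X_raw.shape[0] == 1 and X_raw.size > 1:
        X_raw = X_raw.T
    N = X_raw.shape[0]
    lab = labeled.astype(bool)
    arm1 = lab & (A == 1)
    arm0 = lab & (A == 0)

    model_specs = {
        "pi": (X_raw, A, lab),
        "mu1": (X_raw, Y, arm1),
        "mu0": (X_raw, Y, arm0),
    }
    if with_imputation:
        if S_raw is None:
            raise ValueError("surrogates required for the imputation models")
        W_raw = np.hstack([X_raw, np.asarray(S_raw, dtype=float)])
        model_specs.update({
            "Pi": (W_raw, A, lab),
            "m1": (W_raw, Y, arm1),
            "m0": (W_raw, Y, arm0),
        })

    for k in range(folds.K):
        oof = folds.fold_of != k
        if not (arm1 & oof).any() or not (arm0 & oof).any():
            raise RuntimeError(f"out-of-fold labeled subset of fold {k} lacks an arm")

    lo, hi = expit(-M), expit(M)
    out = {name: np.empty(N) for name in ("pi1", "mu1", "mu0", "Pi1", "m1", "m0")}
    chosen = {}
    for m_idx, (name, (V, target, mask)) in enumerate(model_specs.items()):
        if degrees is not None and name in degrees:
            deg = int(degrees[name])
        else:
            deg = select_degree_cv(V[mask], target[mask], max_degree=max_degree,
                                   order=order, seed=seed + 1000 * (m_idx + 1))
        chosen[name] = deg
        key = {"pi": "pi1", "mu1": "mu1", "mu0": "mu0",
               "Pi": "Pi1", "m1": "m1", "m0": "m0"}[name]
        for k in range(folds.K):
            tr = mask & (folds.fold_of != k)
            te = folds.fold_of == k
            rng = [(V[tr, j].min(), V[tr, j].max()) for j in range(V.shape[1])]
            Btr = bspline_basis(V[tr], deg, order=order, ranges=rng)
            beta = fit_logistic_irls(Btr, target[tr])
            Bte = bspline_basis(V[te], deg, order=order, ranges=rng)
            out[key][te] = predict_proba(Bte, beta)

    for key in out:
        if with_imputation or key in ("pi1", "mu1", "mu0"):
            np.clip(out[key], lo, hi, out=out[key])

    if not with_imputation:
        out["Pi1"][:] = 0.5
        out["m1"][:] = 0.5
        out["m0"][:] = 0.5

    preds = NuisancePredictions(
        pi1=out["pi1"], pi0=1.0 - out["pi1"],
        mu1=out["mu1"], mu0=out["mu0"],
        Pi1=out["Pi1"], Pi0=1.0 - out["Pi1"],
        m1=out["m1"], m0=out["m0"],
        fold_of=folds.fold_of.copy(),
        meta={"degrees": chosen, "trunc_M": M, "order": order,
              "imputation": "spline" if with_imputation else "none"},
    )
    preds.validate_bounds(lo, hi, which=("pi1", "pi0", "mu1", "mu0"))
    return preds


def fit_all_nuisances_lowd(dataset: ObservedDataset, folds: FoldAssignment,
                           M: float = 2.2, order: int = 1,
                           max_degree: int | None = None, seed: int = 0,
                           degrees: dict | None = None) -> NuisancePredictions:
    """Spec'd entry point: all four nuisance models for a semi-supervised
    cohort, out-of-fold for every subject."""
    return fit_spline_nuisances(
        dataset.X[:, 1:], dataset.S, dataset.A, dataset.Y, dataset.labeled,
        folds, M=M, order=order, max_degree=max_degree, seed=seed,
        degrees=degrees,
    )
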