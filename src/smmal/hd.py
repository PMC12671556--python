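"""High-dimensional doubly robust nuisance estimation.

The pipeline, per labeled fold k:

1. imputation lassos on W = (X, S): xi (treatment on W) and zeta_a
   (outcome on W within arm a), plain L1-penalized logistic fits over
   out-of-fold labeled rows;
2. initial propensity/outcome lassos on X per fold *pair* (k1, k2),
   trained on the out-of-two-folds labeled rows (two-level
   cross-fitting);
3. calibrated fits: for target fold k1, the calibrated propensity loss

       gdot(tau(x' beta_init)) * [ (a - A) x' alpha + 1{A=a} e^{(-1)^a x' alpha} ]

   and the calibrated outcome loss

       exp(tau((-1)^a x' alpha_init)) * 1{A=a} * logistic_loss(Y, x' beta)

   are aggregated over folds k2 != k1, each row weighted through the
   initial fit that saw neither k1 nor that row's own fold.  The
   truncation tau(x) = sign(x) min(|x|, 2M) bounds every calibration
   weight in [e^{-2M}, e^{2M}] regardless of how wrong the initial
   model is, which is what removes the sparsity requirement on a
   mis-specified initial fit.  The first-order conditions of these
   losses make the final ATE estimate Neyman-orthogonal to the
   propensity/outcome estimation error;
4. predictions (per subject, from the fits excluding their fold):
   pi(1,x) = g(tau(x'alpha_1)), pi(0,x) = g(tau(-x'alpha_0)),
   mu(a,x) = g(x'beta_a), Pi(1,w) = g(w'xi) with the a = 0 case taken
   as the binary complement, m(a,w) = g(w'zeta_a).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from . import _lasso
from .crossfit import FoldAssignment, fold_pairs
from .datasets import NuisancePredictions, ObservedDataset

__all__ = [
    "TruncationSpec",
    "CoefficientFit",
    "truncate_linpred",
    "logistic_lasso",
    "cv_lambda",
    "calib_ps_objective",
    "calib_or_objective",
    "fit_imputation",
    "fit_initial",
    "fit_calibrated",
    "predict_nuisances_hd",
    "fit_all_nuisances_hd",
]


@dataclass
class TruncationSpec:
    """Linear-predictor truncation at 2M; M=2.2 keeps probabilities in
    roughly [0.1, 0.9] (g(2.2) = 0.900)."""
    M: float = 2.2

    @property
    def cap(self) -> float:
        return 2.0 * self.M


def truncate_linpred(x, spec: TruncationSpec):
    """tau(x) = sign(x) * min(|x|, 2M)."""
    x = np.asarray(x, dtype=float)
    out = np.clip(x, -spec.cap, spec.cap)
    return float(out) if out.ndim == 0 else out


def _gdot(x):
    e = expit(x)
    return e * (1.0 - e)


@dataclass
class CoefficientFit:
    """An L1-penalized coefficient vector; coef[0] multiplies the
    constant-1 column and is never penalized."""
    coef: np.ndarray
    lam: float
    loss_kind: str  # logistic | calib_ps | calib_or
    arm: str        # "0" | "1" | "pooled"
    kkt: float = 0.0
    clamp_count: int = 0
    meta: dict = field(default_factory=dict)

    @property
    def support_size(self) -> int:
        return int(np.count_nonzero(self.coef[1:]))


class SolverDiverged(RuntimeError):
    """The penalized objective is unbounded below at this penalty level
    (possible for the exponential-tilt loss when lam is too small)."""


def _run_solver(design, y, lin_c, log_w, exp_w, exp_s, lam, beta0=None,
                tol=_lasso.KKT_TOL):
    d = design.shape[1]
    pen = np.ones(d)
    pen[0] = 0.0  # intercept unpenalized
    beta, kkt, clamps, status = _lasso.solve_penalized(
        design, y, lin_c, log_w, exp_w, exp_s, lam, pen, beta0=beta0, tol=tol,
        div_cap=500.0)
    if status == 2:
        raise SolverDiverged(
            f"penalized objective unbounded below at lam={lam:.3e}")
    if status != 0:
        raise RuntimeError(f"penalized solver did not converge: KKT residual {kkt:.3e}")
    return beta, kkt, clamps


def logistic_lasso(design: np.ndarray, y: np.ndarray, weights: np.ndarray,
                   lam: float, arm: str = "pooled", beta0=None) -> CoefficientFit:
    """Minimize  sum_i w_i l(y_i, x_i'b) / sum_i w_i + lam * ||b_{-0}||_1."""
    w = np.asarray(weights, dtype=float)
    if (w < 0).any():
        raise ValueError("weights must be nonnegative")
    wsum = w.sum()
    if wsum <= 0:
        raise ValueError("no effective observations")
    z = np.zeros(len(y))
    beta, kkt, clamps = _run_solver(np.ascontiguousarray(design), y, z,
                                    w / wsum, z, 1.0, lam, beta0)
    return CoefficientFit(coef=beta, lam=lam, loss_kind="logistic", arm=arm,
                          kkt=kkt, clamp_count=clamps)


def calib_ps_objective(alpha: np.ndarray, A: np.ndarray, X: np.ndarray,
                       beta_init: np.ndarray, arm: int,
                       spec: TruncationSpec) -> float:
    """Calibrated propensity loss (mean over rows)."""
    w = _gdot(truncate_linpred(X @ beta_init, spec))
    lp = X @ alpha
    s = -1.0 if arm == 1 else 1.0
    ind = (A == arm).astype(float)
    return float(np.mean(w * ((arm - A) * lp + ind * np.exp(np.clip(s * lp, None, _lasso.EXP_CLAMP)))))


def calib_or_objective(beta: np.ndarray, Y: np.ndarray, X: np.ndarray,
                       alpha_init: np.ndarray, arm: int,
                       spec: TruncationSpec) -> float:
    """Calibrated outcome loss on arm-`arm` rows (mean over rows)."""
    s = -1.0 if arm == 1 else 1.0
    w = np.exp(truncate_linpred(s * (X @ alpha_init), spec))
    lp = np.clip(X @ beta, -_lasso.EXP_CLAMP, _lasso.EXP_CLAMP)
    loss = np.log1p(np.exp(lp)) - Y * lp
    return float(np.mean(w * loss))


def _loss_arrays(kind: str, design, y, weights, arm, spec,
                 init_lp=None):
    """Per-observation loss weights for the solver, pre-normalized so the
    smooth objective is the (weighted) mean the estimator definitions use."""
    n = len(y)
    z = np.zeros(n)
    if kind == "logistic":
        wsum = weights.sum()
        return y, z, weights / wsum, z, 1.0
    if kind == "calib_or":
        s = -1.0 if arm == 1 else 1.0
        w = np.exp(np.clip(s * init_lp, -spec.cap, spec.cap)) * weights
        return y, z, w / weights.sum(), z, 1.0
    if kind == "calib_ps":
        gd = _gdot(np.clip(init_lp, -spec.cap, spec.cap)) * weights
        s = -1.0 if arm == 1 else 1.0
        lin_c = gd * (arm - y)
        exp_w = gd * (y == arm)
        norm = weights.sum()
        return y, lin_c / norm, z, exp_w / norm, s
    raise ValueError(kind)


def cv_lambda(design: np.ndarray, y: np.ndarray, weights: np.ndarray,
              loss_kind: str = "logistic", n_folds: int = 10, seed: int = 0,
              n_lambda: int = 50, lambda_min_ratio: float = 1e-2,
              arm: int = 1, spec: TruncationSpec | None = None,
              init_lp: np.ndarray | None = None) -> float:
    """Penalty minimizing the mean out-of-fold loss of the same kind
    along a warm-started log-spaced path; ties go to the larger lam."""
    spec = spec or TruncationSpec()
    weights = np.asarray(weights, dtype=float)
    eff = weights > 0
    if loss_kind != "calib_ps" and len(np.unique(y[eff])) < 2:
        warnings.warn("degenerate response: returning lambda_max")
        yy, lc, lw, ew, es = _loss_arrays(loss_kind, design, y, weights, arm,
                                          spec, init_lp)
        return _lasso.lambda_max(design, yy, lc, lw, ew, es,
                                 np.r_[0.0, np.ones(design.shape[1] - 1)])
    yy, lc, lw, ew, es = _loss_arrays(loss_kind, design, y, weights, arm, spec,
                                      init_lp)
    pen = np.ones(design.shape[1])
    pen[0] = 0.0
    lmax = _lasso.lambda_max(design, yy, lc, lw, ew, es, pen)
    lmax = max(lmax, 1e-10)
    grid = np.geomspace(lmax, lmax * lambda_min_ratio, n_lambda)
    rng = np.random.default_rng(seed)
    n = len(y)
    fold = np.empty(n, dtype=int)
    fold[rng.permutation(n)] = np.arange(n) % n_folds
    cv_loss = np.zeros(n_lambda)
    for f in range(n_folds):
        tr = fold != f
        te = ~tr
        w_tr = weights[tr]
        if w_tr.sum() == 0 or (loss_kind != "calib_ps"
                               and len(np.unique(y[tr & eff])) < 2):
            continue
        a_tr = _loss_arrays(loss_kind, design[tr], y[tr], w_tr, arm, spec,
                            None if init_lp is None else init_lp[tr])
        a_te = _loss_arrays(loss_kind, design[te], y[te], weights[te], arm,
                            spec, None if init_lp is None else init_lp[te])
        beta = None
        Xtr = np.ascontiguousarray(design[tr])
        for li, lam in enumerate(grid):
            try:
                beta, _, _ = _run_solver(Xtr, *_as_args(a_tr), lam, beta0=beta,
                                         tol=1e-5)
            except RuntimeError:
                # unbounded or stalled: this and every smaller lam are
                # out of the admissible range for this training fold
                cv_loss[li:] += 1e6
                break
            lp_te = design[te] @ beta
            cv_loss[li] += _eval_loss(lp_te, *_as_args(a_te))
    best = int(np.argmin(cv_loss + 1e-12 * np.arange(n_lambda)))
    return float(grid[best])


def _as_args(arrs):
    return arrs  # (y, lin_c, log_w, exp_w, exp_s)


def _eval_loss(lp, y, lin_c, log_w, exp_w, exp_s) -> float:
    return float(_lasso._objective(
        np.ascontiguousarray(lp), np.asarray(y, float), np.asarray(lin_c, float),
        np.asarray(log_w, float), np.asarray(exp_w, float), float(exp_s)))


class _Standardizer:
    """Column standardization on the full cohort (intercept untouched);
    coefficients are mapped back to the raw scale."""

    def __init__(self, design: np.ndarray):
        self.mean = design.mean(axis=0)
        self.sd = design.std(axis=0)
        self.mean[0] = 0.0
        self.sd[0] = 1.0
        self.sd[self.sd == 0] = 1.0

    def transform(self, design: np.ndarray) -> np.ndarray:
        return (design - self.mean) / self.sd

    def destandardize(self, beta: np.ndarray) -> np.ndarray:
        raw = beta / self.sd
        raw[0] = beta[0] - np.sum(beta[1:] * self.mean[1:] / self.sd[1:])
        return raw


def fit_imputation(dataset: ObservedDataset, folds: FoldAssignment,
                   lam: float | str = "cv", cv_folds: int = 10, seed: int = 0,
                   standardize: bool = True, feature_subset=None) -> dict:
    """Per-fold imputation lassos on W: xi (A on W) and zeta_a (Y on W,
    arm a), trained on out-of-fold labeled rows.

    ``feature_subset`` optionally restricts the columns of W used
    (e.g. a single surrogate column), the flexible-imputation plug-in.
    """
    W = dataset.W
    if feature_subset is not None:
        keep = np.r_[0, np.asarray(feature_subset)]
        W = W[:, keep]
    std = _Standardizer(W) if standardize else None
    Wd = std.transform(W) if std else W
    lab = dataset.labeled
    A = np.where(lab, dataset.A, 0.0)
    Y = np.where(lab, dataset.Y, 0.0)
    R = lab.astype(float)

    out = {"xi": {}, "zeta1": {}, "zeta0": {}, "std": std}
    lam_by = {}
    for name, (target, wvec) in {
        "xi": (A, R), "zeta1": (Y, R * (A == 1)), "zeta0": (Y, R * (A == 0)),
    }.items():
        # representative out-of-fold training set for the penalty choice
        tr0 = (folds.fold_of != 0) & (wvec > 0)
        if lam == "cv":
            lam_by[name] = cv_lambda(Wd[tr0], target[tr0],
                                     np.ones(tr0.sum()), "logistic",
                                     n_folds=cv_folds, seed=seed)
        else:
            lam_by[name] = float(lam)
        for k in range(folds.K):
            tr = (folds.fold_of != k) & (wvec > 0)
            fit = logistic_lasso(Wd[tr], target[tr], np.ones(tr.sum()),
                                 lam_by[name],
                                 arm=name[-1] if name != "xi" else "pooled")
            fit.meta["fold"] = k
            out[name][k] = fit
    out["lambda"] = lam_by
    return out


def fit_initial(dataset: ObservedDataset, folds: FoldAssignment,
                lam: float | str = "cv", cv_folds: int = 10, seed: int = 0,
                standardize: bool = True) -> dict:
    """Initial propensity/outcome lassos on X per unordered fold pair,
    trained on the out-of-two-folds labeled rows."""
    std = _Standardizer(dataset.X) if standardize else None
    Xd = std.transform(dataset.X) if std else dataset.X
    lab = dataset.labeled
    A = np.where(lab, dataset.A, 0.0)
    Y = np.where(lab, dataset.Y, 0.0)

    specs = {"alpha_init": (A, lab), "beta1_init": (Y, lab & (A == 1)),
             "beta0_init": (Y, lab & (A == 0))}
    lam_by = {}
    # representative out-of-two training set for the penalty choice
    for name, (target, mask) in specs.items():
        tr0 = (folds.fold_of >= 2) & mask
        if lam == "cv":
            lam_by[name] = cv_lambda(Xd[tr0], target[tr0], np.ones(tr0.sum()),
                                     "logistic", n_folds=cv_folds, seed=seed)
        else:
            lam_by[name] = float(lam)

    out = {"alpha_init": {}, "beta1_init": {}, "beta0_init": {}, "std": std,
           "lambda": lam_by}
    for k1, k2 in fold_pairs(folds.K):
        key = frozenset((k1, k2))
        if key in out["alpha_init"]:
            continue
        oot = (folds.fold_of != k1) & (folds.fold_of != k2)
        for name, (target, mask) in specs.items():
            tr = oot & mask
            fit = logistic_lasso(Xd[tr], target[tr], np.ones(tr.sum()),
                                 lam_by[name], arm=name[4] if name[0] == "b" else "pooled")
            out[name][key] = fit
    return out


def fit_calibrated(dataset: ObservedDataset, folds: FoldAssignment,
                   initials: dict, spec: TruncationSpec | None = None,
                   lam: float | str = "cv", cv_folds: int = 10,
                   seed: int = 0) -> dict:
    """Two-level cross-fitted calibrated propensity and outcome fits.

    For target fold k1 the objective sums fold-k2 labeled rows
    (k2 != k1), each weighted through the initial fit trained on
    neither k1 nor k2; propensity losses are normalized by the total
    label count n, outcome losses by the labeled arm-a count outside
    k1 (Eq. 12 conventions).
    """
    spec = spec or TruncationSpec()
    std = initials["std"]
    Xd = std.transform(dataset.X) if std else dataset.X
    lab = dataset.labeled
    A = np.where(lab, dataset.A, 0.0)
    Y = np.where(lab, dataset.Y, 0.0)
    n_lab = dataset.n_labeled
    K = folds.K

    def init_lp(which: str, k1: int, rows: np.ndarray) -> np.ndarray:
        """Linear predictor of the pair-(k1, fold(i)) initial fit."""
        lp = np.empty(rows.sum())
        ridx = np.flatnonzero(rows)
        f_rows = folds.fold_of[ridx]
        for k2 in np.unique(f_rows):
            coef = initials[which][frozenset((k1, int(k2)))].coef
            sel = f_rows == k2
            lp[sel] = Xd[ridx[sel]] @ coef
        return lp

    out = {"alpha1": {}, "alpha0": {}, "beta1": {}, "beta0": {},
           "std": std, "lambda": {}}
    lam_by = {}
    for k1 in range(K):
        oof_lab = lab & (folds.fold_of != k1)
        for a in (0, 1):
            # ---- calibrated propensity for arm a
            rows = oof_lab
            lp_b = init_lp(f"beta{a}_init", k1, rows)
            # Eq. 12 normalizes the PS objective by n, not by |rows|
            wts = np.full(rows.sum(), 1.0)
            yy, lin_c, lw, ew, es = _loss_arrays(
                "calib_ps", Xd[rows], A[rows], wts, a, spec, init_lp=lp_b)
            scale = rows.sum() / n_lab
            lin_c, ew = lin_c * scale, ew * scale
            name = f"alpha{a}"
            if name not in lam_by:
                if lam == "cv":
                    lam_by[name] = cv_lambda(
                        Xd[rows], A[rows], wts, "calib_ps", n_folds=cv_folds,
                        seed=seed, arm=a, spec=spec, init_lp=lp_b) * scale
                else:
                    lam_by[name] = float(lam)
            beta, kkt, clamps = _run_solver(
                np.ascontiguousarray(Xd[rows]), yy, lin_c, lw, ew, es,
                lam_by[name])
            out[name][k1] = CoefficientFit(beta, lam_by[name], "calib_ps",
                                           str(a), kkt, clamps)
            # ---- calibrated outcome for arm a
            rows_a = oof_lab & (A == a)
            lp_a = init_lp("alpha_init", k1, rows_a)
            wts_a = np.ones(rows_a.sum())
            yy, lin_c, lw, ew, es = _loss_arrays(
                "calib_or", Xd[rows_a], Y[rows_a], wts_a, a, spec, init_lp=lp_a)
            bname = f"beta{a}"
            if bname not in lam_by:
                if lam == "cv":
                    lam_by[bname] = cv_lambda(
                        Xd[rows_a], Y[rows_a], wts_a, "calib_or",
                        n_folds=cv_folds, seed=seed, arm=a, spec=spec,
                        init_lp=lp_a)
                else:
                    lam_by[bname] = float(lam)
            beta, kkt, clamps = _run_solver(
                np.ascontiguousarray(Xd[rows_a]), yy, lin_c, lw, ew, es,
                lam_by[bname])
            out[bname][k1] = CoefficientFit(beta, lam_by[bname], "calib_or",
                                            str(a), kkt, clamps)
    out["lambda"] = lam_by
    return out


def predict_nuisances_hd(dataset: ObservedDataset, folds: FoldAssignment,
                         imput: dict, calib: dict,
                         spec: TruncationSpec | None = None) -> NuisancePredictions:
    """Out-of-fold nuisance predictions (Eq. 13 conventions)."""
    spec = spec or TruncationSpec()
    stdX = calib["std"]
    stdW = imput["std"]
    Xd = stdX.transform(dataset.X) if stdX else dataset.X
    Wd = stdW.transform(dataset.W) if stdW else dataset.W
    N = dataset.N
    arrs = {k: np.empty(N) for k in ("pi1", "pi0", "mu1", "mu0", "Pi1", "m1", "m0")}
    for k in range(folds.K):
        te = folds.fold_of == k
        arrs["pi1"][te] = expit(truncate_linpred(Xd[te] @ calib["alpha1"][k].coef, spec))
        arrs["pi0"][te] = expit(truncate_linpred(-(Xd[te] @ calib["alpha0"][k].coef), spec))
        arrs["mu1"][te] = expit(Xd[te] @ calib["beta1"][k].coef)
        arrs["mu0"][te] = expit(Xd[te] @ calib["beta0"][k].coef)
        arrs["Pi1"][te] = expit(Wd[te] @ imput["xi"][k].coef)
        arrs["m1"][te] = expit(Wd[te] @ imput["zeta1"][k].coef)
        arrs["m0"][te] = expit(Wd[te] @ imput["zeta0"][k].coef)
    preds = NuisancePredictions(
        pi1=arrs["pi1"], pi0=arrs["pi0"], mu1=arrs["mu1"], mu0=arrs["mu0"],
        Pi1=arrs["Pi1"], Pi0=1.0 - arrs["Pi1"], m1=arrs["m1"], m0=arrs["m0"],
        fold_of=folds.fold_of.copy(),
        meta={"trunc_M": spec.M, "nuisance": "hd_calibrated"},
    )
    lo, hi = expit(-spec.cap), expit(spec.cap)
    preds.validate_bounds(lo, hi, which=("pi1", "pi0"))
    return preds


def fit_all_nuisances_hd(dataset: ObservedDataset, folds: FoldAssignment,
                         M: float = 2.2, lam: float | str = "cv",
                         cv_folds: int = 10, seed: int = 0,
                         standardize: bool = True) -> NuisancePredictions:
    """Full doubly robust nuisance pipeline (imputation -> initial ->
    calibrated -> predictions)."""
    spec = TruncationSpec(M)
    imput = fit_imputation(dataset, folds, lam=lam, cv_folds=cv_folds,
                           seed=seed, standardize=standardize)
    init = fit_initial(dataset, folds, lam=lam, cv_folds=cv_folds, seed=seed,
                       standardize=standardize)
    calib = fit_calibrated(dataset, folds, init, spec=spec, lam=lam,
                           cv_folds=cv_folds, seed=seed)
    return predict_nuisances_hd(dataset, folds, imput, calib, spec=spec)
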