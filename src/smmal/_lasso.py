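"""L1-penalized M-estimation for the high-dimensional nuisance fits.

One solver covers the three convex losses used by the doubly robust
route.  Per observation i the loss contribution is

    lin_c[i] * lp_i                                  (linear term)
  + log_w[i] * ( log(1 + e^{lp_i}) - y_i * lp_i )    (weighted logistic)
  + exp_w[i] * e^{exp_s * lp_i}                      (exponential tilt)

with lp_i = x_i' beta, plus lam * sum_j pen_j * |beta_j| (intercept
unpenalized via pen_0 = 0).  Plain/weighted logistic lasso uses only
log_w; the calibrated outcome loss is a weighted logistic; the
calibrated propensity loss combines lin_c and exp_w.

The solver is proximal Newton with an inner coordinate descent on the
local quadratic model and objective-based step halving (the
exponential tilt is convex but not Lipschitz-smooth), run in numba.
Exponent arguments are clamped at +-30 and the clamp events counted.
Convergence is certified by the KKT residual of the full objective.
"""

from __future__ import annotations

import numpy as np
from numba import njit

KKT_TOL = 1e-6
MAX_OUTER = 200
EXP_CLAMP = 30.0


@njit(cache=True)
def _grad_curv(lp, y, lin_c, log_w, exp_w, exp_s):
    n = lp.shape[0]
    grad = np.empty(n)
    curv = np.empty(n)
    clamps = 0
    for i in range(n):
        l = lp[i]
        gi = lin_c[i]
        ci = 0.0
        if log_w[i] != 0.0:
            if l > EXP_CLAMP:
                sig = 1.0
            elif l < -EXP_CLAMP:
                sig = 0.0
            else:
                sig = 1.0 / (1.0 + np.exp(-l))
            gi += log_w[i] * (sig - y[i])
            ci += log_w[i] * sig * (1.0 - sig)
        if exp_w[i] != 0.0:
            arg = exp_s * l
            if arg > EXP_CLAMP:
                arg = EXP_CLAMP
                clamps += 1
            ev = np.exp(arg)
            gi += exp_s * exp_w[i] * ev
            ci += exp_w[i] * ev
        grad[i] = gi
        curv[i] = ci
    return grad, curv, clamps


@njit(cache=True)
def _objective(lp, y, lin_c, log_w, exp_w, exp_s):
    n = lp.shape[0]
    f = 0.0
    for i in range(n):
        l = lp[i]
        f += lin_c[i] * l
        if log_w[i] != 0.0:
            # log(1 + e^l) - y*l, computed stably
            if l > EXP_CLAMP:
                lse = l
            elif l < -EXP_CLAMP:
                lse = 0.0
            else:
                lse = np.log1p(np.exp(l))
            f += log_w[i] * (lse - y[i] * l)
        if exp_w[i] != 0.0:
            arg = exp_s * l
            if arg > EXP_CLAMP:
                arg = EXP_CLAMP
            f += exp_w[i] * np.exp(arg)
    return f


@njit(cache=True)
def _kkt_residual(Xg, beta, lam, pen):
    """Max violation of the stationarity conditions; Xg = X' grad."""
    d = beta.shape[0]
    worst = 0.0
    for j in range(d):
        g = Xg[j]
        if pen[j] == 0.0:
            r = abs(g)
        elif beta[j] > 0.0:
            r = abs(g + lam * pen[j])
        elif beta[j] < 0.0:
            r = abs(g - lam * pen[j])
        else:
            r = abs(g) - lam * pen[j]
            if r < 0.0:
                r = 0.0
        if r > worst:
            worst = r
    return worst


@njit(cache=True)
def _solve(X, y, lin_c, log_w, exp_w, exp_s, lam, pen, beta,
           tol, max_outer, inner_sweeps, inner_tol, div_cap):
    # status: 0 converged, 1 iteration limit, 2 diverged (objective
    # unbounded below at this penalty level)
    n, d = X.shape
    lp = X @ beta
    clamps = 0
    kkt = np.inf
    fcur = _objective(lp, y, lin_c, log_w, exp_w, exp_s)
    for j in range(d):
        fcur += lam * pen[j] * abs(beta[j])
    for _ in range(max_outer):
        grad, curv, c = _grad_curv(lp, y, lin_c, log_w, exp_w, exp_s)
        clamps += c
        Xg = X.T @ grad
        kkt = _kkt_residual(Xg, beta, lam, pen)
        if kkt <= tol:
            return beta, kkt, clamps, 0
        # quadratic model around lp; inner coordinate descent on delta
        a = np.empty(d)
        for j in range(d):
            s = 0.0
            for i in range(n):
                s += curv[i] * X[i, j] * X[i, j]
            a[j] = s + 1e-12
        delta = np.zeros(d)
        s_lp = np.zeros(n)  # X @ delta
        # glmnet-style active-set cycling: full sweeps only to seed and
        # to verify convergence of the restricted sweeps
        active = np.zeros(d, dtype=np.bool_)
        for j in range(d):
            active[j] = beta[j] != 0.0 or pen[j] == 0.0
        mode_full = True
        for _ in range(inner_sweeps):
            maxstep = 0.0
            for j in range(d):
                if not mode_full and not active[j]:
                    continue
                cj = Xg[j]
                for i in range(n):
                    cj += curv[i] * s_lp[i] * X[i, j]
                v_old = beta[j] + delta[j]
                z = a[j] * v_old - cj
                t = lam * pen[j]
                if z > t:
                    v = (z - t) / a[j]
                elif z < -t:
                    v = (z + t) / a[j]
                else:
                    v = 0.0
                step = v - v_old
                if step > 2.0:
                    step = 2.0
                elif step < -2.0:
                    step = -2.0
                if step != 0.0:
                    delta[j] += step
                    active[j] = True
                    for i in range(n):
                        s_lp[i] += step * X[i, j]
                    if abs(step) > maxstep:
                        maxstep = abs(step)
            if mode_full:
                if maxstep < inner_tol:
                    break
                mode_full = False
            elif maxstep < inner_tol:
                mode_full = True  # confirm with one full sweep
        # step halving on the true objective
        t_step = 1.0
        accepted = False
        for _ in range(30):
            lp_new = lp + t_step * s_lp
            fnew = _objective(lp_new, y, lin_c, log_w, exp_w, exp_s)
            for j in range(d):
                fnew += lam * pen[j] * abs(beta[j] + t_step * delta[j])
            if fnew <= fcur + 1e-14 * (1.0 + abs(fcur)):
                for j in range(d):
                    beta[j] = beta[j] + t_step * delta[j]
                lp = lp_new
                fcur = fnew
                accepted = True
                break
            t_step *= 0.5
        l1 = 0.0
        for j in range(d):
            l1 += abs(beta[j])
        if l1 > div_cap:
            return beta, kkt, clamps, 2
        if not accepted:
            # no descent direction left at this precision
            grad, curv, c = _grad_curv(lp, y, lin_c, log_w, exp_w, exp_s)
            Xg = X.T @ grad
            kkt = _kkt_residual(Xg, beta, lam, pen)
            if kkt <= tol * 10.0:
                return beta, kkt, clamps, 0
            return beta, kkt, clamps, 1
    grad, curv, c = _grad_curv(lp, y, lin_c, log_w, exp_w, exp_s)
    Xg = X.T @ grad
    kkt = _kkt_residual(Xg, beta, lam, pen)
    if kkt <= tol:
        return beta, kkt, clamps, 0
    return beta, kkt, clamps, 1


def solve_penalized(X, y, lin_c, log_w, exp_w, exp_s, lam, pen,
                    beta0=None, tol=KKT_TOL, max_outer=MAX_OUTER,
                    inner_sweeps=50, inner_tol=1e-8, div_cap=1e4):
    """Python entry point.

    Returns (beta, kkt_residual, clamp_count, status) with status 0 for
    KKT-certified convergence, 1 for iteration limit, 2 for a diverging
    iterate (the penalized objective is unbounded below at this lam).
    """
    X = np.ascontiguousarray(X, dtype=np.float64)
    n, d = X.shape
    beta = np.zeros(d) if beta0 is None else np.asarray(beta0, dtype=np.float64).copy()
    args = [np.ascontiguousarray(np.asarray(v, dtype=np.float64))
            for v in (y, lin_c, log_w, exp_w)]
    return _solve(X, *args, float(exp_s), float(lam),
                  np.ascontiguousarray(np.asarray(pen, dtype=np.float64)),
                  beta, tol, max_outer, inner_sweeps, inner_tol, float(div_cap))


def intercept_only(y, lin_c, log_w, exp_w, exp_s, n_iter=100):
    """1-D Newton for the unpenalized intercept of the null model."""
    b = 0.0
    ones = np.ones_like(np.asarray(log_w, dtype=float))
    y = np.asarray(y, dtype=float)
    lin_c = np.asarray(lin_c, dtype=float)
    log_w = np.asarray(log_w, dtype=float)
    exp_w = np.asarray(exp_w, dtype=float)
    for _ in range(n_iter):
        lp = b * ones
        grad, curv, _ = _grad_curv(lp, y, lin_c, log_w, exp_w, float(exp_s))
        g, h = grad.sum(), curv.sum() + 1e-12
        step = np.clip(g / h, -2.0, 2.0)
        b -= step
        if abs(step) < 1e-12:
            break
    return b


def lambda_max(X, y, lin_c, log_w, exp_w, exp_s, pen):
    """Smallest lam at which all penalized coefficients are zero."""
    b0 = intercept_only(y, lin_c, log_w, exp_w, exp_s)
    lp = np.full(X.shape[0], b0)
    grad, _, _ = _grad_curv(lp, np.asarray(y, float), np.asarray(lin_c, float),
                            np.asarray(log_w, float), np.asarray(exp_w, float),
                            float(exp_s))
    Xg = X.T @ grad
    pen = np.asarray(pen, dtype=float)
    with np.errstate(divide="ignore"):
        vals = np.abs(Xg[pen > 0]) / pen[pen > 0]
    return float(vals.max()) if vals.size else 0.0
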