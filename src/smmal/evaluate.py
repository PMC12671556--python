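"""Replicated simulation harness.

Runs every requested estimator on the *same* synthetic cohort per
replicate (pairwise common random numbers, which stabilizes relative-
efficiency ratios at modest replicate counts) and aggregates bias,
empirical SD, mean standard error, CI coverage against the scenario's
true ATE, and relative efficiency (ratio of empirical variances,
benchmark over method).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .crossfit import assign_folds_safe
from .datasets import NuisancePredictions, SimulatedTruth
from .estimator import (ensemble_estimate, smmal_estimate,
                        supervised_estimate, unsupervised_estimate)
from .hd import fit_all_nuisances_hd
from .simulate import ALPHA_TABLE, AUC_LEVELS, SimulationConfig, generate
from .splines import fit_all_nuisances_lowd

__all__ = ["ReplicateSummary", "run_replicates", "nuisance_mse", "heatmap_grid"]

SPLINE_METHODS = {"smmal", "sl_dml", "ensemble"}
HD_METHODS = {"smmal_dr"}


@dataclass
class ReplicateSummary:
    method: str
    n_reps: int
    bias: float
    sd: float
    mean_se: float
    coverage: float
    re_vs: dict = field(default_factory=dict)
    n_failures: int = 0
    deltas: np.ndarray | None = None
    meta: dict = field(default_factory=dict)


def _run_one(data, truth, methods, seed, K, M, hd_K, hd_cv_folds, ul_max_degree):
    """All requested estimators on one cohort; shared nuisances where the
    estimators share models."""
    out = {}
    need_spline = SPLINE_METHODS & set(methods)
    if need_spline:
        folds = assign_folds_safe(data.N, K, seed, data.R, data.A)
        preds = fit_all_nuisances_lowd(data, folds, M=M, seed=seed)
        ssl = smmal_estimate(data, preds)
        sl = supervised_estimate(data, preds)
        if "smmal" in methods:
            out["smmal"] = ssl
        if "sl_dml" in methods:
            out["sl_dml"] = sl
        if "ensemble" in methods:
            out["ensemble"] = ensemble_estimate(ssl, sl)
    if "ul" in methods:
        out["ul"] = unsupervised_estimate(data, K=K, M=M, seed=seed,
                                          max_degree=ul_max_degree)
    if "smmal_dr" in methods:
        folds = assign_folds_safe(data.N, hd_K, seed, data.R, data.A,
                                  two_level=True)
        preds = fit_all_nuisances_hd(data, folds, M=M, cv_folds=hd_cv_folds,
                                     seed=seed)
        out["smmal_dr"] = smmal_estimate(data, preds, method="smmal_dr")
    return out


def run_replicates(config: SimulationConfig, methods, n_reps: int,
                   base_seed: int = 0, K: int = 10, M: float = 2.2,
                   hd_K: int = 5, hd_cv_folds: int = 10,
                   ul_max_degree: int = 22,
                   benchmark: str = "sl_dml") -> dict:
    """Replicate the design ``n_reps`` times (seeds base_seed+r) and
    summarize each estimator against the scenario's true ATE."""
    if n_reps < 2:
        raise ValueError("need at least 2 replicates")
    methods = list(methods)
    deltas = {m: [] for m in methods}
    ses = {m: [] for m in methods}
    covers = {m: [] for m in methods}
    failures = {m: 0 for m in methods}
    delta_star = None
    for r in range(n_reps):
        cfg = replace(config, seed=base_seed + r)
        data, truth = generate(cfg)
        delta_star = truth.delta_star
        try:
            ests = _run_one(data, truth, methods, base_seed + r, K, M,
                            hd_K, hd_cv_folds, ul_max_degree)
        except Exception:
            for m in methods:
                failures[m] += 1
            continue
        for m in methods:
            est = ests[m]
            deltas[m].append(est.delta)
            ses[m].append(est.se)
            covers[m].append(est.covers(truth.delta_star))
    out = {}
    variances = {m: np.var(deltas[m], ddof=1) for m in methods if len(deltas[m]) > 1}
    for m in methods:
        d = np.asarray(deltas[m])
        re_vs = {b: float(variances[b] / variances[m])
                 for b in methods if b != m and b in variances and m in variances}
        out[m] = ReplicateSummary(
            method=m, n_reps=len(d),
            bias=float(d.mean() - delta_star),
            sd=float(d.std(ddof=1)),
            mean_se=float(np.mean(ses[m])),
            coverage=float(np.mean(covers[m])),
            re_vs=re_vs, n_failures=failures[m], deltas=d,
            meta={"delta_star": delta_star, "base_seed": base_seed,
                  "benchmark": benchmark},
        )
    return out


def nuisance_mse(preds: NuisancePredictions, truth: SimulatedTruth,
                 Pi_star: tuple | None = None,
                 m_star: tuple | None = None) -> dict:
    """Max-over-arms root mean squared model distance
    ||h_hat - h*||_2 = max_a sqrt(mean (h_hat(a,.) - h*(a,.))^2).

    The imputation truths have no closed form in general; pass MC
    regression oracles (Pi1*, Pi0*) / (m1*, m0*) to include them.
    """
    def maxrmse(pairs):
        return float(max(np.sqrt(np.mean((a - b) ** 2)) for a, b in pairs))

    out = {
        "pi": maxrmse([(preds.pi1, truth.pi_star),
                       (preds.pi0, 1.0 - truth.pi_star)]),
        "mu": maxrmse([(preds.mu1, truth.mu1_star),
                       (preds.mu0, truth.mu0_star)]),
    }
    if Pi_star is not None:
        out["Pi"] = maxrmse([(preds.Pi1, Pi_star[0]), (preds.Pi0, Pi_star[1])])
    if m_star is not None:
        out["m"] = maxrmse([(preds.m1, m_star[0]), (preds.m0, m_star[1])])
    return out


def _auc_of(scenario: str, which: str, alpha: float) -> float:
    for lev, a in zip(AUC_LEVELS, ALPHA_TABLE[scenario][which]):
        if abs(a - alpha) < 1e-9:
            return lev
    return float("nan")


def heatmap_grid(alpha_grid_A, alpha_grid_Y, scenario: str, n_reps: int,
                 seed: int = 0, methods=("smmal", "sl_dml", "ul"),
                 N: int = 10_000, n_expected: int = 500, K: int = 10,
                 benchmark: str = "sl_dml", **kwargs) -> pd.DataFrame:
    """Surrogate-quality grid: one run_replicates call per (alpha_A,
    alpha_Y) cell; long-format table of RE and coverage per method."""
    rows = []
    for ia, aA in enumerate(alpha_grid_A):
        for iy, aY in enumerate(alpha_grid_Y):
            cfg = SimulationConfig(scenario=scenario, N=N,
                                   n_expected=n_expected, alpha_A=aA,
                                   alpha_Y=aY, seed=0)
            res = run_replicates(cfg, methods, n_reps,
                                 base_seed=seed + 10_000 * (ia * len(alpha_grid_Y) + iy),
                                 K=K, benchmark=benchmark, **kwargs)
            for m, summ in res.items():
                rows.append({
                    "alpha_A": aA, "alpha_Y": aY,
                    "auc_A": _auc_of(scenario, "A", aA),
                    "auc_Y": _auc_of(scenario, "Y", aY),
                    "method": m,
                    "re": summ.re_vs.get(benchmark, float("nan")),
                    "coverage": summ.coverage,
                    "bias": summ.bias, "sd": summ.sd,
                    "mean_se": summ.mean_se, "n_reps": summ.n_reps,
                })
    return pd.DataFrame(rows)
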