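"""Synthetic cohorts for the semi-supervised ATE problem.

Two families of data-generating processes are provided:

* a low-dimensional smooth design with a single Uniform(0,1) confounder
  and bounded smooth propensity/outcome curves, and
* high-dimensional logistic designs with an AR(1) Gaussian confounder
  vector and sparse coefficient vectors at graded signal strengths
  (0.5 strong, 0.25 moderately strong, 0.125 moderately weak,
  0.0625 weak), in linear and second-order-interaction variants that
  create deliberate model mis-specification scenarios.

Surrogates mimic phenotyping-algorithm scores in (0,1): a mixture Beta
mechanism draws ``S ~ Beta(alpha+u, 1)`` when the latent label is 1 and
``S ~ Beta(1, alpha+u)`` when it is 0, where ``u`` is a Uniform(0,1)
transform of the confounder.  Larger ``alpha`` separates the two
mixture components and raises the marginal AUC of the surrogate; the
``ALPHA_TABLE`` below records the calibrated values for AUC levels
0.80/0.90/0.95/0.99/0.999.

Labels are missing completely at random: ``R ~ Bernoulli(rho)`` from a
stream independent of everything else.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.special import betaln, expit, ndtr
from scipy.stats import rankdata

from .datasets import ObservedDataset, SimulatedTruth

__all__ = [
    "SimulationConfig",
    "SCENARIOS",
    "ALPHA_TABLE",
    "AUC_LEVELS",
    "generate",
    "gen_lowd",
    "gen_hd",
    "gen_surrogate",
    "mcar_labels",
    "surrogate_auc",
    "alpha_for_auc",
    "delta_star_hd",
]

SCENARIOS = (
    "lowd_smooth",
    "hd_linear_linear",
    "hd_psinteraction_orlinear",
    "hd_pslinear_orinteraction",
)

AUC_LEVELS = (0.80, 0.90, 0.95, 0.99, 0.999)

# Calibrated mixture-Beta concentration per scenario / surrogate / AUC level.
ALPHA_TABLE = {
    "lowd_smooth": {
        "A": (1.39, 1.99, 2.54, 3.86, 5.49),
        "Y": (1.39, 1.96, 2.57, 3.80, 5.70),
    },
    "hd_linear_linear": {
        "A": (1.36, 1.99, 2.54, 3.80, 5.64),
        "Y": (1.33, 1.96, 2.51, 3.89, 5.55),
    },
    "hd_psinteraction_orlinear": {
        "A": (1.36, 1.96, 2.54, 3.80, 5.55),
        "Y": (1.39, 1.93, 2.54, 3.74, 5.52),
    },
    "hd_pslinear_orinteraction": {
        "A": (1.36, 1.96, 2.54, 3.80, 5.55),
        "Y": (1.39, 1.93, 2.54, 3.74, 5.52),
    },
}

# named substreams: perturbing one generator knob only touches its stream
_STREAMS = {"X": 0, "A": 1, "Y": 2, "S_A": 3, "S_Y": 4, "R": 5, "ORACLE": 6}


def component_rng(seed: int, name: str) -> np.random.Generator:
    """Independent generator for one named component of the simulation."""
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(_STREAMS[name],))
    )


def alpha_for_auc(scenario: str, which: str, auc: float) -> float:
    """Look up the calibrated Beta concentration for a target AUC level."""
    levels = ALPHA_TABLE[scenario][which]
    for lev, a in zip(AUC_LEVELS, levels):
        if abs(lev - auc) < 1e-9:
            return a
    raise KeyError(f"no calibration for AUC={auc}; choose from {AUC_LEVELS}")


@dataclass
class SimulationConfig:
    """Design of one synthetic cohort.

    ``n_expected`` is the expected number of labels (rho = n_expected/N).
    ``alpha_A``/``alpha_Y`` set surrogate quality (see ``ALPHA_TABLE``).
    ``smooth_form`` selects between the two admissible readings of the
    low-dimensional smooth curve: ``"sq_denom"`` (default) uses
    ``1 - 1.2/(3 - X^2)``, ``"shift_sq"`` uses ``1 - 1.2/(3 - X)^2``;
    both respect treatment positivity and both have a zero true ATE by
    the X -> 1-X symmetry of the design.
    """

    scenario: str
    N: int = 10_000
    n_expected: int = 500
    alpha_A: float = 2.54
    alpha_Y: float = 2.57
    p: int = 500
    seed: int = 0
    smooth_form: str = "sq_denom"

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if not 0 < self.n_expected < self.N:
            raise ValueError("need 0 < n_expected < N")
        if self.alpha_A <= 0 or self.alpha_Y <= 0:
            raise ValueError("Beta concentrations must be positive")
        if self.scenario == "lowd_smooth":
            self.p = 1
        elif self.p < 3:
            raise ValueError("high-dimensional models reference X1..X3; need p >= 3")
        if self.smooth_form not in ("sq_denom", "shift_sq"):
            raise ValueError("smooth_form must be 'sq_denom' or 'shift_sq'")

    @property
    def rho(self) -> float:
        return self.n_expected / self.N


def _smooth_curve(x: np.ndarray, form: str) -> np.ndarray:
    if form == "sq_denom":
        return 1.0 - 1.2 / (3.0 - x**2)
    return 1.0 - 1.2 / (3.0 - x) ** 2


def gen_surrogate(value, u, alpha: float, rng: np.random.Generator) -> np.ndarray:
    """Mixture-Beta surrogate draw given the latent binary label.

    ``Beta(alpha+u, 1)`` under ``value == 1``, ``Beta(1, alpha+u)``
    under ``value == 0``; the two branches are mirror images
    (``Beta(1,b) = 1 - Beta(b,1)`` in law).
    """
    value = np.asarray(value)
    u = np.asarray(u, dtype=float)
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if np.any((u <= 0) | (u >= 1)):
        raise ValueError("u must lie strictly in (0, 1)")
    conc = alpha + u
    s1 = rng.beta(conc, 1.0)
    s0 = rng.beta(1.0, conc)
    return np.where(value == 1, s1, s0)


def mcar_labels(N: int, rho: float, rng: np.random.Generator) -> np.ndarray:
    """i.i.d. Bernoulli(rho) label indicators, independent of the cohort."""
    if not 0 < rho < 1:
        raise ValueError("rho must lie strictly in (0, 1)")
    return (rng.random(N) < rho).astype(int)


def _assemble(config, X_raw, u, pi, mu1, mu0, delta, delta_se, meta):
    """Draw (A, Y, S, R) from the latent models and mask the labels."""
    rng_A = component_rng(config.seed, "A")
    rng_Y = component_rng(config.seed, "Y")
    rng_SA = component_rng(config.seed, "S_A")
    rng_SY = component_rng(config.seed, "S_Y")
    rng_R = component_rng(config.seed, "R")

    N = config.N
    A = (rng_A.random(N) < pi).astype(float)
    muA = np.where(A == 1, mu1, mu0)
    Y = (rng_Y.random(N) < muA).astype(float)
    S_A = gen_surrogate(A, u, config.alpha_A, rng_SA)
    S_Y = gen_surrogate(Y, u, config.alpha_Y, rng_SY)
    R = mcar_labels(N, config.rho, rng_R)

    X = np.column_stack([np.ones(N), X_raw])
    S = np.column_stack([S_A, S_Y])
    data = ObservedDataset(
        X=X, S=S, R=R,
        A=np.where(R == 1, A, np.nan),
        Y=np.where(R == 1, Y, np.nan),
    )
    truth = SimulatedTruth(
        delta_star=delta, pi_star=pi, mu1_star=mu1, mu0_star=mu0,
        A_full=A, Y_full=Y, delta_star_se=delta_se, meta=meta,
    )
    return data, truth


def gen_lowd(config: SimulationConfig):
    """Low-dimensional smooth design: X ~ U(0,1), pi* = mu*(1,.) smooth.

    ``mu*(0,X)`` is the treated curve evaluated at ``1-X``; since X is
    symmetric about 1/2, the true ATE is exactly zero.
    """
    if config.scenario != "lowd_smooth":
        raise ValueError("gen_lowd requires scenario 'lowd_smooth'")
    rng_X = component_rng(config.seed, "X")
    X_raw = rng_X.random(config.N)
    pi = _smooth_curve(X_raw, config.smooth_form)
    mu1 = pi.copy()
    mu0 = _smooth_curve(1.0 - X_raw, config.smooth_form)
    meta = {"scenario": config.scenario, "smooth_form": config.smooth_form}
    return _assemble(config, X_raw, X_raw, pi, mu1, mu0, 0.0, 0.0, meta)


def _hd_forms(scenario: str):
    ps_form = "interaction" if scenario == "hd_psinteraction_orlinear" else "linear"
    or_form = "interaction" if scenario == "hd_pslinear_orinteraction" else "linear"
    return ps_form, or_form


def _hd_pi(X123: np.ndarray, ps_form: str) -> np.ndarray:
    lin = 0.5 * X123[:, 0] + 0.25 * X123[:, 1] + 0.125 * X123[:, 2]
    if ps_form == "interaction":
        lin = lin * (1 + 0.0625 * X123[:, 0] + 0.125 * X123[:, 1] - 0.5 * X123[:, 2])
    return expit(lin)


def _hd_mu(X123: np.ndarray, or_form: str):
    lin = 0.1 + 0.25 * X123[:, 0] + 0.125 * X123[:, 1] + 0.0625 * X123[:, 2]
    if or_form == "interaction":
        scale = 1 + 0.0625 * X123[:, 0] + 0.125 * X123[:, 1] - 0.5 * X123[:, 2]
        return expit(lin * scale), expit(-lin * scale)
    return expit(lin), expit(-lin)


def _ar1_draw(rng: np.random.Generator, N: int, p: int) -> np.ndarray:
    """X1 = U1, Xj = 0.5 X_{j-1} + 0.75 Uj with U iid standard normal."""
    U = rng.standard_normal((N, p))
    X = np.empty_like(U)
    X[:, 0] = U[:, 0]
    for j in range(1, p):
        X[:, j] = 0.5 * X[:, j - 1] + 0.75 * U[:, j]
    return X


@lru_cache(maxsize=None)
def delta_star_hd(or_form: str, n_mc: int = 1_000_000, seed: int = 2_000_000) -> tuple:
    """Monte-Carlo oracle of the true ATE under an hd outcome model.

    Only X1..X3 enter the outcome curves, so the oracle is independent
    of p.  Returns (estimate, standard error).
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAMS["ORACLE"],)))
    X123 = _ar1_draw(rng, n_mc, 3)
    mu1, mu0 = _hd_mu(X123, or_form)
    diff = mu1 - mu0
    return float(diff.mean()), float(diff.std(ddof=1) / np.sqrt(n_mc))


def gen_hd(config: SimulationConfig):
    """High-dimensional AR(1) Gaussian design with sparse logistic models."""
    if config.scenario == "lowd_smooth":
        raise ValueError("gen_hd requires one of the hd scenarios")
    ps_form, or_form = _hd_forms(config.scenario)
    rng_X = component_rng(config.seed, "X")
    X_raw = _ar1_draw(rng_X, config.N, config.p)
    pi = _hd_pi(X_raw[:, :3], ps_form)
    mu1, mu0 = _hd_mu(X_raw[:, :3], or_form)
    u = ndtr(X_raw[:, 0])  # Phi(X1) ~ Uniform(0,1) marginally
    delta, delta_se = delta_star_hd(or_form)
    meta = {"scenario": config.scenario, "ps_form": ps_form, "or_form": or_form}
    return _assemble(config, X_raw, u, pi, mu1, mu0, delta, delta_se, meta)


def generate(config: SimulationConfig):
    """Dispatch to the scenario's generator."""
    if config.scenario == "lowd_smooth":
        return gen_lowd(config)
    return gen_hd(config)


def _latent_and_u(scenario: str, which: str, n: int, rng: np.random.Generator,
                  smooth_form: str = "sq_denom"):
    """Draw (latent label, covariate transform u) under the scenario's law."""
    if scenario == "lowd_smooth":
        x = rng.random(n)
        u = x
        pi = _smooth_curve(x, smooth_form)
        mu1 = pi
        mu0 = _smooth_curve(1.0 - x, smooth_form)
    else:
        X123 = _ar1_draw(rng, n, 3)
        u = ndtr(X123[:, 0])
        ps_form, or_form = _hd_forms(scenario)
        pi = _hd_pi(X123, ps_form)
        mu1, mu0 = _hd_mu(X123, or_form)
    A = (rng.random(n) < pi).astype(int)
    if which == "A":
        return A, u
    muA = np.where(A == 1, mu1, mu0)
    Y = (rng.random(n) < muA).astype(int)
    return Y, u


def surrogate_auc(scenario: str, alpha: float, which: str = "A",
                  n_mc: int = 1_000_000, seed: int = 0,
                  method: str = "rank") -> float:
    """Monte-Carlo marginal AUC of the surrogate for its latent label.

    ``method="rank"`` draws a cohort and computes the Mann-Whitney rank
    AUC of the surrogate score.  ``method="closed_form"`` averages the
    conditional closed form ``P(Beta(a,1) > Beta(1,b)) = 1 - a*B(a, b+1)``
    over independent case/control covariate draws (weighted by the class
    probabilities), serving as an independent check of the rank route.
    """
    if which not in ("A", "Y"):
        raise ValueError("which must be 'A' or 'Y'")
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if n_mc < 10_000:
        raise ValueError("n_mc must be at least 1e4")
    rng = np.random.default_rng(seed)
    if method == "rank":
        label, u = _latent_and_u(scenario, which, n_mc, rng)
        s = gen_surrogate(label, u, alpha, rng)
        n1 = int(label.sum())
        n0 = n_mc - n1
        ranks = rankdata(s)
        return float((ranks[label == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))
    if method == "closed_form":
        # subsample covariate pairs; the conditional AUC is exact given (u_i, u_j)
        m = min(n_mc, 4000)
        lab_i, u_i = _latent_and_u(scenario, which, m, rng)
        lab_j, u_j = _latent_and_u(scenario, which, m, rng)
        # class-membership weights from fresh label draws (Monte Carlo over
        # the covariate tilt of cases vs controls)
        w1 = lab_i.astype(float)
        w0 = 1.0 - lab_j.astype(float)
        a = alpha + u_i[:, None]
        b = alpha + u_j[None, :]
        cond = 1.0 - np.exp(np.log(a) + betaln(a, b + 1.0))
        num = (w1[:, None] * w0[None, :] * cond).sum()
        den = w1.sum() * w0.sum()
        return float(num / den)
    raise ValueError("method must be 'rank' or 'closed_form'")
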