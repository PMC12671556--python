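"""Core data containers for semi-supervised ATE estimation.

The observed cohort consists of N i.i.d. subjects with always-observed
confounders ``X`` and surrogates ``S``, and gold-standard treatment ``A``
and outcome ``Y`` available only on the labeled subset ``R == 1``
(missing completely at random).  Masked entries of ``A``/``Y`` are stored
as NaN so that any arithmetic that accidentally touches an unlabeled
subject's treatment or outcome propagates NaN instead of silently
contributing zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ObservedDataset",
    "SimulatedTruth",
    "NuisancePredictions",
    "ATEEstimate",
]


@dataclass
class ObservedDataset:
    """Semi-supervised cohort ``(R, R·A, R·Y, X, S)``.

    Attributes
    ----------
    X : (N, p+1) float array
        Confounder design including a constant-1 first column.
    S : (N, q) float array
        Surrogates, observed for every subject.
    R : (N,) int array
        Label indicator; ``A`` and ``Y`` are defined iff ``R == 1``.
    A, Y : (N,) float arrays
        Treatment and outcome; NaN where ``R == 0``.
    """

    X: np.ndarray
    S: np.ndarray
    R: np.ndarray
    A: np.ndarray
    Y: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.S = np.asarray(self.S, dtype=float)
        self.R = np.asarray(self.R, dtype=int)
        self.A = np.asarray(self.A, dtype=float)
        self.Y = np.asarray(self.Y, dtype=float)
        if self.X.ndim != 2 or not np.allclose(self.X[:, 0], 1.0):
            raise ValueError("X must be 2-D with a constant-1 first column")
        n_lab = int(self.R.sum())
        # a fully labeled cohort (R identically 1) is the complete-data
        # limit in which the estimator reduces to AIPW
        if n_lab == 0:
            raise ValueError("need at least one labeled subject")
        lab = self.R == 1
        if np.isnan(self.A[lab]).any() or np.isnan(self.Y[lab]).any():
            raise ValueError("labeled subjects must have observed A and Y")
        # keep the masking contract airtight regardless of how the arrays
        # were assembled upstream
        self.A = np.where(lab, self.A, np.nan)
        self.Y = np.where(lab, self.Y, np.nan)

    @property
    def N(self) -> int:
        return self.X.shape[0]

    @property
    def n_labeled(self) -> int:
        return int(self.R.sum())

    @property
    def rho_hat(self) -> float:
        return self.n_labeled / self.N

    @property
    def p(self) -> int:
        """Number of confounders excluding the intercept column."""
        return self.X.shape[1] - 1

    @property
    def q(self) -> int:
        return self.S.shape[1]

    @property
    def W(self) -> np.ndarray:
        """Stacked ``[X, S]`` design of shape (N, p+q+1)."""
        return np.hstack([self.X, self.S])

    @property
    def labeled(self) -> np.ndarray:
        return self.R == 1

    def to_frame(self) -> pd.DataFrame:
        cols = {"id": np.arange(self.N), "R": self.R, "A": self.A, "Y": self.Y}
        for j in range(self.q):
            cols[f"S_{'A' if j == 0 else 'Y' if j == 1 else j}"] = self.S[:, j]
        for j in range(1, self.X.shape[1]):
            cols[f"X{j}"] = self.X[:, j]
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ObservedDataset":
        s_cols = [c for c in df.columns if c.startswith("S_")]
        x_cols = sorted(
            (c for c in df.columns if c.startswith("X") and c[1:].isdigit()),
            key=lambda c: int(c[1:]),
        )
        N = len(df)
        X = np.column_stack([np.ones(N)] + [df[c].to_numpy(float) for c in x_cols])
        S = df[s_cols].to_numpy(float)
        return cls(X=X, S=S, R=df["R"].to_numpy(int),
                   A=df["A"].to_numpy(float), Y=df["Y"].to_numpy(float))

    @classmethod
    def from_csv(cls, path) -> "ObservedDataset":
        return cls.from_frame(pd.read_csv(path))


@dataclass
class SimulatedTruth:
    """Ground truth attached to a synthetic cohort.

    ``delta_star`` is the true ATE; for Monte-Carlo oracles its standard
    error is recorded in ``delta_star_se`` (0.0 when analytic).
    ``A_full``/``Y_full`` are the latent treatment/outcome of every
    subject before label masking.
    """

    delta_star: float
    pi_star: np.ndarray
    mu1_star: np.ndarray
    mu0_star: np.ndarray
    A_full: np.ndarray
    Y_full: np.ndarray
    delta_star_se: float = 0.0
    meta: dict = field(default_factory=dict)

    def to_csv(self, path) -> None:
        df = pd.DataFrame({
            "id": np.arange(len(self.pi_star)),
            "pi_star": self.pi_star,
            "mu1_star": self.mu1_star,
            "mu0_star": self.mu0_star,
            "A_full": self.A_full,
            "Y_full": self.Y_full,
        })
        with open(path, "w") as fh:
            fh.write(f"# delta_star={self.delta_star!r} "
                     f"delta_star_se={self.delta_star_se!r}\n")
            df.to_csv(fh, index=False)


@dataclass
class NuisancePredictions:
    """Out-of-fold nuisance values for every subject.

    ``pi1[i]`` etc. come from the fit trained without ``fold_of[i]``.
    ``Pi1/Pi0`` and ``m1/m0`` are the surrogate-assisted imputation
    models on W; ``pi`` and ``mu`` are the propensity and outcome models
    on X alone.
    """

    pi1: np.ndarray
    pi0: np.ndarray
    mu1: np.ndarray
    mu0: np.ndarray
    Pi1: np.ndarray
    Pi0: np.ndarray
    m1: np.ndarray
    m0: np.ndarray
    fold_of: np.ndarray
    meta: dict = field(default_factory=dict)

    def _arrays(self):
        return {"pi1": self.pi1, "pi0": self.pi0, "mu1": self.mu1,
                "mu0": self.mu0, "Pi1": self.Pi1, "Pi0": self.Pi0,
                "m1": self.m1, "m0": self.m0}

    def validate_bounds(self, lo: float, hi: float, which=("pi1", "pi0")) -> None:
        for name, arr in self._arrays().items():
            if name in which:
                if arr.min() < lo - 1e-12 or arr.max() > hi + 1e-12:
                    raise ValueError(f"{name} outside [{lo}, {hi}]")


@dataclass
class ATEEstimate:
    """Point estimate with influence-function-based inference.

    ``V`` estimates the asymptotic variance of sqrt(n)·(delta - Delta*),
    where n is the number of labels; the CI is
    ``delta ± z_{alpha/2} · sqrt(V / n)``.
    """

    delta: float
    influence: np.ndarray
    V: float
    n: int
    N: int
    rho_hat: float
    ci_low: float
    ci_high: float
    level: float
    method: str
    meta: dict = field(default_factory=dict)

    @property
    def se(self) -> float:
        return float(np.sqrt(self.V / self.n))

    def covers(self, truth: float) -> bool:
        return bool(self.ci_low <= truth <= self.ci_high)

    def to_dict(self) -> dict:
        return {
            "method": self.method, "delta": self.delta, "se": self.se,
            "ci": [self.ci_low, self.ci_high], "level": self.level,
            "n": self.n, "N": self.N, "rho_hat": self.rho_hat,
            **{k: v for k, v in self.meta.items()
               if isinstance(v, (int, float, str, bool))},
        }
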