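"""K-fold partitioning for (two-level) cross-fitting.

The whole cohort — labeled and unlabeled subjects together — is split
into K folds of near-equal size; the label indicator is MCAR, so no
stratification is needed or wanted.  Two-level cross-fitting
additionally needs, for every ordered fold pair (k1, k2), the training
set that excludes both folds: the initial-stage fit trained there is
later applied to fold-k2 rows inside the calibrated objective that
targets fold k1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FoldAssignment", "assign_folds", "assign_folds_safe", "fold_pairs"]


@dataclass
class FoldAssignment:
    K: int
    fold_of: np.ndarray  # (N,) values in 0..K-1
    seed: int

    @property
    def N(self) -> int:
        return len(self.fold_of)

    def fold(self, k: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of == k)

    def out_of_fold(self, k: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of != k)

    def out_of_two(self, k1: int, k2: int) -> np.ndarray:
        return np.flatnonzero((self.fold_of != k1) & (self.fold_of != k2))

    def _check(self) -> None:
        sizes = np.bincount(self.fold_of, minlength=self.K)
        assert sizes.sum() == self.N and (sizes > 0).all()
        assert sizes.max() - sizes.min() <= 1


def assign_folds(N: int, K: int, seed: int) -> FoldAssignment:
    """Uniform random balanced partition of 0..N-1 into K folds."""
    if K < 3:
        raise ValueError("two-level cross-fitting needs K >= 3")
    if K > N:
        raise ValueError("cannot split N subjects into more than N folds")
    rng = np.random.default_rng(seed)
    fold_of = np.empty(N, dtype=int)
    # deal fold labels 0..K-1 cyclically onto a random permutation:
    # fold sizes differ by at most one
    fold_of[rng.permutation(N)] = np.arange(N) % K
    fa = FoldAssignment(K=K, fold_of=fold_of, seed=seed)
    fa._check()
    return fa


def fold_pairs(K: int) -> list:
    """All K(K-1) ordered fold pairs (k1, k2), k2 != k1."""
    if K < 3:
        raise ValueError("two-level cross-fitting needs K >= 3")
    return [(k1, k2) for k1 in range(K) for k2 in range(K) if k2 != k1]


def _arms_ok(fold_of: np.ndarray, K: int, R: np.ndarray, A: np.ndarray,
             two_level: bool) -> bool:
    """Every training subset must contain labeled rows of both arms."""
    lab = R == 1
    a_lab = A[lab]
    f_lab = fold_of[lab]

    def both_arms(mask):
        sub = a_lab[mask]
        return sub.size > 0 and (sub == 1).any() and (sub == 0).any()

    for k in range(K):
        if not both_arms(f_lab != k):
            return False
    if two_level:
        for k1 in range(K):
            for k2 in range(k1 + 1, K):
                if not both_arms((f_lab != k1) & (f_lab != k2)):
                    return False
    return True


def assign_folds_safe(N: int, K: int, seed: int, R: np.ndarray, A: np.ndarray,
                      two_level: bool = False, max_tries: int = 20) -> FoldAssignment:
    """Draw a partition, re-drawing (seed+1, ...) if some training subset
    would lack a treatment arm among its labeled rows.

    Raises after ``max_tries`` degenerate draws — at that point the
    labeled data are too thin for arm-specific nuisance fits and the
    user should reduce K.
    """
    for t in range(max_tries):
        fa = assign_folds(N, K, seed + t)
        if _arms_ok(fa.fold_of, K, R, A, two_level):
            return fa
    raise RuntimeError(
        f"no admissible {K}-fold split in {max_tries} tries: some "
        "out-of-fold labeled subset lacks a treatment arm"
    )
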