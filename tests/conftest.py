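import numpy as np
import pytest

from smmal.crossfit import assign_folds_safe
from smmal.simulate import SimulationConfig, generate


@pytest.fixture(scope="session")
def lowd_cohort():
    """Small low-dimensional cohort with ground truth."""
    cfg = SimulationConfig(scenario="lowd_smooth", N=4000, n_expected=400,
                           alpha_A=2.54, alpha_Y=2.57, seed=7)
    data, truth = generate(cfg)
    return cfg, data, truth


@pytest.fixture(scope="session")
def lowd_folds(lowd_cohort):
    _, data, _ = lowd_cohort
    return assign_folds_safe(data.N, 10, 7, data.R, data.A)


@pytest.fixture(scope="session")
def hd_cohort():
    """Small high-dimensional cohort (correct PS and OR models)."""
    cfg = SimulationConfig(scenario="hd_linear_linear", N=1500, n_expected=400,
                           p=20, alpha_A=2.54, alpha_Y=2.51, seed=5)
    data, truth = generate(cfg)
    return cfg, data, truth


@pytest.fixture(scope="session")
def hd_folds(hd_cohort):
    _, data, _ = hd_cohort
    return assign_folds_safe(data.N, 5, 5, data.R, data.A, two_level=True)


def oracle_preds(data, truth, fold_of=None, Pi1=None, m1=None, m0=None):
    """NuisancePredictions built from the simulation truth, with
    optionally overridden imputation models (default: uninformative
    constants, which the method tolerates by design)."""
    from smmal.datasets import NuisancePredictions

    N = data.N
    half = np.full(N, 0.5)
    return NuisancePredictions(
        pi1=truth.pi_star.copy(), pi0=1 - truth.pi_star,
        mu1=truth.mu1_star.copy(), mu0=truth.mu0_star.copy(),
        Pi1=half.copy() if Pi1 is None else Pi1,
        Pi0=(half.copy() if Pi1 is None else 1 - Pi1),
        m1=half.copy() if m1 is None else m1,
        m0=half.copy() if m0 is None else m0,
        fold_of=np.zeros(N, dtype=int) if fold_of is None else fold_of,
        meta={"oracle": True},
    )
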