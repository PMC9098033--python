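import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import trajmix as tm

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def small_lmm_spec(p_extra: int = 3, sigma2: float = 16.0, d: float = 0.5):
    """One-cluster spec with a handful of covariates; used with the
    brute-force ML oracle."""
    names = [f"x{k}" for k in range(p_extra)]
    beta = np.array([[20.0, -3.0] + [1.5, 0.8, 2.0][:p_extra]])
    return tm.SyntheticSpec(
        covariate_names=names,
        pi=[1.0],
        beta=beta,
        d=[d],
        sigma2=[sigma2],
        n_subjects=100,
        retention=(1.0, 0.9, 0.8),
    )


def two_cluster_spec(n_subjects: int = 200):
    """Two well-separated flat clusters (intercepts 0 and 50)."""
    return tm.SyntheticSpec(
        covariate_names=["x0", "x1"],
        pi=[0.5, 0.5],
        beta=np.array([[0.0, 0.0, 1.0, 0.0], [50.0, 0.0, 0.0, -1.0]]),
        d=[0.2, 0.2],
        sigma2=[25.0, 25.0],
        n_subjects=n_subjects,
        retention=(1.0, 0.95, 0.9),
    )


def medium_mixture_spec(n_subjects: int = 150):
    """Compact three-cluster spec for EM-behavior tests."""
    return tm.SyntheticSpec(
        covariate_names=["x0", "x1", "x2", "x3"],
        pi=[0.4, 0.4, 0.2],
        beta=np.array(
            [
                [10.0, -1.0, 1.0, 0.0, 0.0, 0.0],
                [30.0, -15.0, 0.0, 2.0, 0.0, 0.0],
                [2.0, 20.0, 0.0, 0.0, -3.0, 0.0],
            ]
        ),
        d=[0.5, 0.5, 0.5],
        sigma2=[36.0, 49.0, 49.0],
        n_subjects=n_subjects,
        retention=(1.0, 0.95, 0.85),
    )


@pytest.fixture(scope="session")
def small_cohort():
    return tm.simulate_cohort(small_lmm_spec(), seed=7)


@pytest.fixture(scope="session")
def two_cluster_cohort():
    return tm.simulate_cohort(two_cluster_spec(), seed=11)


@pytest.fixture(scope="session")
def medium_cohort():
    return tm.simulate_cohort(medium_mixture_spec(), seed=3)


@pytest.fixture(scope="session")
def taag_cohort():
    return tm.simulate_cohort(tm.default_taag_spec(), seed=5)
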