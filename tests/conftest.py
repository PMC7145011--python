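import numpy as np
import pytest

from costtraj import SimConfig, simulate_cohort

#: Well-separated 3-group quadratic study design used across tests:
#: rate levels ~25 / ~9 / ~3 counts per month with distinct shapes and a
#: common 20% zero-inflation mass.
RECOVERY_PI = (0.40, 0.35, 0.25)
RECOVERY_BETA = np.array([
    [3.2, 0.8, -0.8],
    [2.2, -1.0, 1.2],
    [0.8, 0.5, 0.0],
])
RECOVERY_GAMMA = np.log(0.2 / 0.8) * np.ones((3, 1))


def recovery_config(n_patients: int, seed: int) -> SimConfig:
    return SimConfig(
        n_patients=n_patients,
        pi=list(RECOVERY_PI),
        beta=RECOVERY_BETA.copy(),
        gamma=RECOVERY_GAMMA.copy(),
        zero_inflation="constant",
        group_covariates=False,
        seed=seed,
    )


@pytest.fixture(scope="session")
def cohort3():
    """Medium cohort from the 3-group design: (patients, matrix, labels)."""
    return simulate_cohort(recovery_config(250, seed=11))


@pytest.fixture(scope="session")
def study_cohort():
    """Default six-archetype study cohort at a reduced size."""
    return simulate_cohort(SimConfig(n_patients=300, seed=7))
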