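import numpy as np
import pytest

import cardiorenal as cr


@pytest.fixture(scope="session")
def small_cohort():
    """Error-free synthetic cohort, default archetypes, 3 rounds x 400 women."""
    cfg = cr.default_config("female", n_per_round=400, seed=11)
    cfg.rounds = cfg.rounds[:3]
    return cr.generate_cohort(cfg)


@pytest.fixture(scope="session")
def separated_cohort():
    """Four archetypes separated by 8 within-cluster SDs, n=2000, one round."""
    cfg = cr.CohortConfig(
        sex="female",
        archetypes=cr.separated_archetypes(4, separation=8.0),
        n_per_round=2000,
        rounds=[("r1", 2000.0)],
        seed=7,
    )
    return cr.generate_cohort(cfg)


@pytest.fixture(scope="session")
def separated_blobs():
    """Four spherical Gaussian blobs in 10-d, 6-SD separated, with labels."""
    rng = np.random.default_rng(5)
    centers = np.zeros((4, 10))
    for j in range(4):
        centers[j, j % 10] = j * 6.0
        centers[j, (j + 3) % 10] = 6.0 * ((j % 2) * 2 - 1)
    labels = rng.integers(0, 4, size=1200)
    X = centers[labels] + rng.standard_normal((1200, 10))
    return X, labels
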