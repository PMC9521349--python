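import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from cosegnet.cohort import MutationMatrix
from cosegnet.synthetic import default_cohort_model, sample_cohort


@pytest.fixture(scope="session")
def planted_model():
    return default_cohort_model(seed=1)


@pytest.fixture(scope="session")
def planted_cohort(planted_model):
    """One sampled default cohort (7707 patients), shared across tests."""
    return sample_cohort(planted_model, seed=20240)


@pytest.fixture()
def toy_matrix():
    """6 patients × 3 genes with hand-checkable counts."""
    values = np.array(
        [
            [1, 1, 0],
            [1, 0, 0],
            [0, 1, 0],
            [0, 0, 0],
            [1, 1, 0],
            [0, 0, 0],
        ]
    )
    return MutationMatrix.from_arrays(
        [f"p{i}" for i in range(6)], ["A", "B", "C"], values
    )


def random_binary_matrix(rng, n, m, correlated=True):
    """Random cohort with a latent factor so columns are dependent."""
    base = rng.random((n, m)) < rng.uniform(0.1, 0.5, size=m)
    if correlated:
        latent = rng.random(n) < 0.3
        flip = rng.random((n, m)) < 0.4
        base = np.where(flip & latent[:, None], 1, base)
    return MutationMatrix.from_arrays(
        [f"p{i}" for i in range(n)], [f"G{j}" for j in range(m)], base.astype(int)
    )
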