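import logging

import numpy as np
import pytest

from fatsas.synthetic import PhantomParams, generate_cohort

logging.getLogger("fatsas").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_params():
    return PhantomParams(n_subjects=6, seed=42)


@pytest.fixture(scope="session")
def small_cohort(small_params):
    """Six voxelized subjects; shared across tests (read-only)."""
    return generate_cohort(small_params)


@pytest.fixture(scope="session")
def midsize_cohort():
    params = PhantomParams(n_subjects=20, seed=7)
    return params, generate_cohort(params)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_monotone_landmarks(rng, labels, lo=30.0, hi=220.0, decreasing=True):
    """Strictly monotone landmark z positions with random irregular gaps."""
    gaps = rng.uniform(0.5, 2.0, size=len(labels) - 1)
    pos = np.concatenate([[0.0], np.cumsum(gaps)])
    pos = lo + (hi - lo) * pos / pos[-1]
    return pos[::-1].copy() if decreasing else pos
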