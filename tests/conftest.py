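"""Shared fixtures: reference synthetic cohorts and extraction results.

The 300-sample, 4-signature, 5%-noise cohort is the package's reference
study condition; it is generated once per session and shared by the
extraction, consensus and acceptance tests.
"""

import numpy as np
import pytest

from cnasig import simulate_cohort
from cnasig.consensus import build_consensus
from cnasig.extraction import run_all_methods

REFERENCE_SEED = 7


@pytest.fixture(scope="session")
def cohort300():
    """300 samples, 4 planted signatures (one diploid-like), 5% noise."""
    return simulate_cohort(n_samples=300, k=4, noise_level=0.05, seed=REFERENCE_SEED)


@pytest.fixture(scope="session")
def cohort300_zero_noise():
    return simulate_cohort(n_samples=300, k=4, noise_level=0.0, seed=REFERENCE_SEED)


@pytest.fixture(scope="session")
def small_cohort():
    """120 samples, 3 planted signatures, zero noise — fast exact-recovery runs."""
    return simulate_cohort(n_samples=120, k=3, noise_level=0.0, seed=3)


@pytest.fixture(scope="session")
def reference_pool(cohort300):
    """All four backends run on the reference cohort."""
    pool, diags = run_all_methods(cohort300.features, seed=REFERENCE_SEED)
    return pool, diags


@pytest.fixture(scope="session")
def reference_consensus(cohort300, reference_pool):
    pool, _ = reference_pool
    return build_consensus(cohort300.features, pool)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
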