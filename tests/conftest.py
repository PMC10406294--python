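import numpy as np
import pytest

import spdmap as sm


def make_spd(rng, n, scale=1.0):
    """Random well-conditioned SPD matrix."""
    A = rng.normal(size=(n, n))
    return scale * (A @ A.T / n + 0.5 * np.eye(n))


@pytest.fixture
def rng():
    return np.random.default_rng(20260918)


@pytest.fixture(scope="session")
def small_cohort():
    """M=8, K=6 synthetic cohort with heat-kernel truth and mild noise."""
    spec = sm.SyntheticSpec(M_regions=8, K_subjects=6, seed=3,
                            noise_sigma=0.05, subject_jitter=0.1)
    cohort, truth = sm.generate_cohort(spec)
    return cohort, truth


@pytest.fixture(scope="session")
def noiseless_cohort():
    """M=8, K=5 noiseless heat-kernel cohort (exact recovery possible)."""
    spec = sm.SyntheticSpec(M_regions=8, K_subjects=5, seed=11,
                            noise_sigma=0.0, subject_jitter=0.15)
    cohort, truth = sm.generate_cohort(spec)
    return cohort, truth
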