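import numpy as np
import pytest
import scipy.sparse as sp

from topicphewas import (
    CodeCountMatrix,
    SimulationConfig,
    simulate_cohort,
    simulate_code_counts,
)


@pytest.fixture(scope="session")
def small_config():
    """Small but non-trivial four-wave cohort with a strong planted effect."""
    return SimulationConfig(
        n_subjects_per_wave=(120, 110, 115, 105),
        n_topics_true=5,
        n_codes=50,
        alpha0=0.1,
        beta_phi=0.05,
        effect_size=5.0,
        codes_per_subject_mean=25.0,
        seed=101,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config)


@pytest.fixture(scope="session")
def small_counts(small_config, small_cohort):
    return simulate_code_counts(small_cohort, small_config)


def make_counts(dense, subject_ids=None, vocab=None):
    dense = np.asarray(dense)
    n, v = dense.shape
    return CodeCountMatrix(
        subject_ids or [f"s{i}" for i in range(n)],
        vocab or [f"c{j}" for j in range(v)],
        sp.csr_matrix(dense),
    )
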