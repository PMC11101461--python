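import numpy as np
import pytest

from snfmark.synthetic import CohortSpec, generate_cohort, generate_interaction_tables


@pytest.fixture(scope="session")
def small_spec():
    """A fast cohort retaining all structural features of the full design."""
    return CohortSpec(n_patients=48, n_subtypes=4, n_methylation=200,
                      n_mrna=200, n_mirna=150, effect_size=3.0, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return generate_cohort(small_spec)


@pytest.fixture(scope="session")
def small_interactions(small_spec, small_cohort):
    return generate_interaction_tables(small_cohort, small_spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def block_similarity(sizes, within, between, jitter=0.0, seed=0):
    """Symmetric block-structured similarity matrix for clustering tests."""
    rng = np.random.default_rng(seed)
    n = sum(sizes)
    S = np.full((n, n), between, dtype=float)
    start = 0
    for size, w in zip(sizes, np.broadcast_to(within, len(sizes))):
        S[start:start + size, start:start + size] = w
        start += size
    if jitter:
        noise = rng.uniform(-jitter, jitter, size=(n, n))
        S += (noise + noise.T) / 2
    np.fill_diagonal(S, 1.0)
    return S
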