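import pytest

import emgwean as ew
from emgwean.synth import DESIGNED_INFORMATIVE

# Desk-scale study conditions: 600 s recordings are the shortest that give
# two overlapping 300-s analysis windows after edge trimming.
SHORT_DURATION = 600.0


def small_spec(seed, n_success=2, n_failure=2, **kw):
    return ew.CohortSpec(n_success=n_success, n_failure=n_failure,
                         duration=SHORT_DURATION, seed=seed, **kw)


@pytest.fixture(scope="session")
def demo_recording():
    """One success-group recording shared by read-only tests."""
    return ew.generate_cohort(small_spec(7, n_success=1, n_failure=0))[0]


@pytest.fixture(scope="session")
def demo_clean(demo_recording):
    return ew.preprocess_recording(demo_recording)


@pytest.fixture(scope="session")
def demo_derived(demo_clean):
    return ew.derive_signals(demo_clean)


@pytest.fixture(scope="session")
def contrast_cohorts():
    """Feature matrices for 20 seeded 15+15 cohorts (shared by the
    end-to-end recovery checks; this is the expensive fixture)."""
    matrices = []
    for seed in range(100, 120):
        spec = ew.CohortSpec(n_success=15, n_failure=15,
                             duration=SHORT_DURATION, seed=seed)
        matrices.append(ew.cohort_feature_matrix(ew.generate_cohort(spec)))
    return matrices


@pytest.fixture(scope="session")
def designed_features():
    return [f"mean_{b}" for b in DESIGNED_INFORMATIVE]
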