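import numpy as np
import pytest

from shiftwork.hypnogram import EpochSeries
from shiftwork.synthetic import CohortSpec, generate_cohort


def make_series(states, t0_zt=0.0, animal_id="test", schedule_tag=None):
    """EpochSeries from a compact state string like 'WWNNNR'."""
    return EpochSeries(
        animal_id=animal_id,
        t0_zt=t0_zt,
        states=list(states),
        schedule_tag=schedule_tag,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small, fast cohort reused by pipeline-level tests."""
    spec = CohortSpec(n_rw=5, n_aw=5, days_baseline=2, days_work=3, seed=7)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def default_cohort():
    """One full-size cohort at the default study conditions."""
    return generate_cohort(CohortSpec(seed=0))
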