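import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from earlygsd import (
    AllocationSpec,
    CorrelationSpec,
    FollowUpSchedule,
    RecruitmentSpec,
)


@pytest.fixture
def sched_3_6_12():
    """3/6/12-month follow-up in 3-month base units."""
    return FollowUpSchedule([1.0, 2.0, 4.0])


@pytest.fixture
def rec_fixed_188():
    """Fixed-rate recruitment of 188 participants over 24 months (8 units)."""
    return RecruitmentSpec("fixed", 188.0, 8.0)


@pytest.fixture
def rec_decreasing_188():
    return RecruitmentSpec("decreasing", 188.0, 8.0)


@pytest.fixture
def uniform_half():
    return CorrelationSpec("uniform", 0.5)


@pytest.fixture
def alloc_equal():
    return AllocationSpec(0.5)


@pytest.fixture
def rng():
    return np.random.default_rng(20240216)


def random_monotone_counts(rng, s, n_min=5.0, n_max=200.0):
    """Strictly positive, non-increasing per-occasion counts."""
    raw = rng.uniform(n_min, n_max, size=s)
    return np.sort(raw)[::-1].copy()
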