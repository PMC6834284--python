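import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_cohort():
    """Ten patients with a mix of deaths and censorings."""
    from neep.cohort import ClinicalCohort
    times = [120, 340, 90, 800, 450, 1000, 60, 700, 250, 500]
    events = [1, 0, 1, 0, 1, 0, 1, 1, 1, 0]
    ids = [f"P{i:02d}" for i in range(10)]
    return ClinicalCohort(np.array(ids, dtype=object),
                          np.array(times, float), np.array(events))
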