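import numpy as np
import pytest

from organotrope.patterns import PatternLabel
from organotrope.riskset import CohortPatient


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_patient(pid, diagnosis, exit_, pattern="none", t_first=None, **cov):
    label = PatternLabel(pattern, t_first)
    return CohortPatient(pid, diagnosis, exit_, label, dict(cov))


@pytest.fixture
def small_cohort():
    """Six patients with staggered follow-up and two events."""
    return [
        make_patient("a", 0, 4000, "bone_only", 1000, ER=1),
        make_patient("b", 100, 5000, "visceral_only", 2400, ER=0),
        make_patient("c", 200, 6000, ER=1),
        make_patient("d", 900, 3000, ER=1),
        make_patient("e", 1500, 7000, ER=0),
        make_patient("f", 2600, 6500, ER=1),
    ]
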