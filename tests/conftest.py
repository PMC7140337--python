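import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from cogscreen.cohort import Group, Sex, StudyDataset, SubjectRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def small_dataset() -> StudyDataset:
    """Six hand-written subjects, one per interesting corner."""
    return StudyDataset(
        records=[
            SubjectRecord("s1", Group.NC, 72, 14, Sex.F, 28, 30, moca_z=0.4),
            SubjectRecord("s2", Group.NC, 80, 10, Sex.M, 24, 29, moca_z=-0.9),
            SubjectRecord("s3", Group.NF, 69, 13, Sex.F, 27, 29, moca_z=0.1),
            SubjectRecord("s4", Group.MILD, 77, 11, Sex.M, 22, 28, moca_z=-1.4),
            SubjectRecord("s5", Group.MILD, 83, 8, Sex.F, 19, 26, moca_z=-2.2),
            SubjectRecord("s6", Group.MAJOR, 85, 7, Sex.M, 12, 21, moca_z=-3.1),
        ],
        provenance="fixture",
    )
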