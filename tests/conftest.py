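import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from slowstep import GaitParams, ProtocolSegment, synth_cohort, synth_session, train_detector

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cohort3():
    """The default 3-participant virtual cohort used throughout the suite."""
    return synth_cohort(3, seed=42)


@pytest.fixture(scope="session")
def short_session():
    """A small session (one slow-walk block between stands) for cheap tests."""
    protocol = [
        ProtocolSegment("stand", 5.0),
        ProtocolSegment("walk30", 30.0, cadence_spm=30),
        ProtocolSegment("stand", 5.0),
    ]
    return synth_session(protocol, GaitParams(seed=7), participant_id="S1")


@pytest.fixture(scope="session")
def transition_model(cohort3):
    """Transition-matrix detector trained on the first two participants."""
    return train_detector(cohort3[:2], variant="transition_matrix", seed=42)


@pytest.fixture(scope="session")
def raw_model(cohort3):
    """Raw-acceleration detector trained on the first two participants."""
    return train_detector(cohort3[:2], variant="raw_accel", seed=42)
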