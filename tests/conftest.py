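import numpy as np
import pytest

from beliefsim.models import (
    BeliefTrajectory,
    FeedbackOrder,
    Framing,
    Referent,
    simulate_trajectory,
)
from beliefsim.synthetic_data import canonical_feedback_sequences


@pytest.fixture(scope="session")
def pos_first():
    return canonical_feedback_sequences()[0]


@pytest.fixture(scope="session")
def neg_first():
    return canonical_feedback_sequences()[1]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def rw_trajectory(pos_first):
    """A model-3 run simulated at known parameters."""
    return simulate_trajectory(
        3, [0.45, 300.0, 0.12, 1.3], pos_first, seed=7, participant_id="rw0"
    )


@pytest.fixture(scope="session")
def bayes_trajectory(pos_first):
    """A model-1 run simulated at known parameters."""
    return simulate_trajectory(
        1, [8.0, 10.0, 1.5], pos_first, seed=11, participant_id="by0"
    )


def make_trajectory(reports, feedback, pid="t0", framing=Framing.TOP_HALF):
    return BeliefTrajectory(
        participant_id=pid,
        referent=Referent.SELF,
        framing=framing,
        feedback=np.asarray(feedback, dtype=int),
        reports=np.asarray(reports, dtype=float),
        feedback_order=FeedbackOrder.POSITIVE_FIRST,
    )


@pytest.fixture(scope="session")
def make_traj():
    return make_trajectory
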