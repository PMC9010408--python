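import numpy as np
import pandas as pd
import pytest

from socialug import task_engine
from socialug.synth import CohortSpec, synth_sessions


def make_session(offers, choices, phis=None, faces=None, pot=1000):
    """Hand-built session table for small oracle tests."""
    n = len(offers)
    phis = phis if phis is not None else [0.5] * n
    faces = faces if faces is not None else [5] * n
    offers = np.asarray(offers, int)
    choices = np.asarray(choices, int)
    return pd.DataFrame({
        "trial": np.arange(1, n + 1),
        "block": np.ones(n, int),
        "face_index": faces,
        "phi": phis,
        "offer_pence": offers,
        "other_pence": pot - offers,
        "choice": choices,
        "outcome_self": offers * choices,
        "outcome_other": (pot - offers) * choices,
        "reaction_face_index": faces,
        "rt_ms": np.nan,
    })


@pytest.fixture(scope="session")
def small_cohort():
    """Six identity-perception responders playing full closed-loop sessions."""
    spec = CohortSpec(n_participants=6).identity_perception()
    return synth_sessions(spec, seed=123)


@pytest.fixture(scope="session")
def one_session(small_cohort):
    return small_cohort[0].session
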