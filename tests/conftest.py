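import numpy as np
import pandas as pd
import pytest

from prapp.covariates import build_design_matrix
from prapp.records import ParticipantRecord


@pytest.fixture
def toy_design():
    """Small separable-ish design: one informative binary column, n=60."""
    rng = np.random.default_rng(42)
    y = np.array([0] * 30 + [1] * 30)
    frame = pd.DataFrame(
        {
            "outcome": y,
            "signal": np.where(y == 1, "yes", "no"),
            "noise": rng.choice(["a", "b"], size=60),
        }
    )
    return build_design_matrix(
        frame, grouping_spec={"signal": ("no", "yes"), "noise": ("a", "b")}
    )


def eligible_user(pid=0, **kw):
    """A record that passes every selection filter as a current PrEP user."""
    defaults = dict(
        participant_id=pid,
        age_years=35,
        prep_status="current",
        hiv_status_confirmed_negative="yes",
        sdu_6m="yes",
        condom_use_category="0%",
        n_sex_partners_6m_category="2-3",
    )
    defaults.update(kw)
    return ParticipantRecord(**defaults)


def eligible_non_user(pid=0, **kw):
    kw.setdefault("prep_status", "never")
    return eligible_user(pid, **kw)
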