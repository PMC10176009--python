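import numpy as np
import pandas as pd
import pytest

import peirs_risk as pr


@pytest.fixture(scope="session")
def default_schedule():
    return pr.make_experience_schedule(seed=123)


@pytest.fixture(scope="session")
def sim_dataset(default_schedule):
    params = pr.PeirsParams(alpha_q=0.3, alpha_s=0.3, beta=0.2,
                            gamma0=0.05, gamma1=0.05)
    return pr.simulate_subject(params, default_schedule, seed=456)


def make_trial_log(rows):
    """Build a completed experience trial log from short tuples:
    (trial_type, left, right, chosen, reward); right='' for forced."""
    recs = []
    for i, (ttype, left, right, chosen, reward) in enumerate(rows, start=1):
        recs.append({
            "trial": i, "block": 1, "stim_set": 1, "trial_type": ttype,
            "option_left": left, "option_right": right,
            "chosen": chosen, "reward": reward,
        })
    return pd.DataFrame(recs)


@pytest.fixture
def trial_log_builder():
    return make_trial_log
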