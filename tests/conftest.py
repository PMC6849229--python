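import logging
import warnings

import numpy as np
import pandas as pd
import pytest

import trialmorb as tm

# arviz emits a refactor FutureWarning on import; irrelevant to these tests
warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")
logging.getLogger("trialmorb").setLevel(logging.WARNING)


@pytest.fixture(scope="session")
def rules():
    return tm.default_rule_table()


@pytest.fixture(scope="session")
def small_config():
    """Two-condition study small enough for fast end-to-end runs."""
    return tm.study_config(
        ["asthma", "osteoarthritis"],
        n_trials=3,
        participants_per_trial=250,
        community_n=1500,
        seed=202,
    )


@pytest.fixture(scope="session")
def community_sim(small_config, rules):
    return tm.simulate_community(small_config, rules)


@pytest.fixture(scope="session")
def trial_sim(small_config, rules):
    return tm.simulate_trials(small_config, rules)


def meds_frame(rows):
    """Build a medication table from (person_id, atc, name, route, date) tuples."""
    return pd.DataFrame(rows, columns=tm.coding.MEDICATION_COLUMNS)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
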