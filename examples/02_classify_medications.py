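"""Classify drug-defined comorbidities for a handful of medication records.

Shows the three coding steps: name→ATC assignment, the trial exposure
window (drugs started on or before randomisation), and prefix-based
classification with index-condition suppression.
"""

import pandas as pd

from trialmorb import assign_atc, classify, trial_window_filter
from trialmorb.coding import MEDICATION_COLUMNS

meds = pd.DataFrame(
    [
        ("p1", "A02BC01", "", "", "2014-05-01"),          # proton-pump inhibitor
        ("p1", "", "salbutamol", "inhaled", "2013-11-20"),  # name-coded, maps to R03
        ("p1", "", "sertraline", "oral", "2015-01-10"),     # antidepressant
        ("p1", "C07AB07", "", "", "2015-09-01"),           # started AFTER randomisation
        ("p1", "", "xyzzy-elixir", "oral", "2014-01-01"),   # unresolvable name
    ],
    columns=MEDICATION_COLUMNS,
)

coded = assign_atc(meds)
print("assigned ATC codes:", coded["atc_code"].tolist())

randomisation = pd.Series(pd.to_datetime(["2015-06-01"]), index=["p1"])
windowed = trial_window_filter(coded, randomisation)
print(f"records kept by the trial window: {len(windowed)} of {len(meds)}")

profile = classify(windowed, index_condition="asthma")
print(f"flags: {sorted(profile.flags)}  count: {profile.count}")

# The beta-blocker is dropped (post-randomisation), the unknown name maps to
# UNKNOWN and contributes nothing, and the salbutamol record cannot flag
# asthma/COPD because asthma is the index condition — so the count is 2
# (acid-related disorders + affective disorders).
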