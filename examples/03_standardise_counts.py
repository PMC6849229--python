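"""Aggregate person-level counts and directly standardise to trial weights.

Community count distributions are built per age-sex stratum (the
disclosure-safe export unit) and re-weighted to the pooled trial age-sex
composition, so the community and trial sides are compared on the same
demographic footing.
"""

import numpy as np
import pandas as pd

from trialmorb import (
    aggregate_counts,
    classify_cohort,
    community_window_filter,
    simulate_community,
    simulate_trials,
    standardise_community,
    study_config,
    trial_age_sex_weights,
)

config = study_config(["copd"], n_trials=2, participants_per_trial=400,
                      community_n=4000, seed=3)
patients, meds, _ = simulate_community(config)
profiles = classify_cohort(community_window_filter(meds), patients)

dists = aggregate_counts(profiles)
print(f"{len(dists)} (condition, age-band, sex) count distributions")

participants, _, _ = simulate_trials(config)
weights = trial_age_sex_weights(participants)
print("trial age-sex weights (top 3):")
print(weights.sort_values(ascending=False).head(3).round(3).to_string())

standardised = standardise_community({d.stratum: d for d in dists}, weights)
crude = np.array([sum(d.n_at_count[k] for d in dists) for k in range(13)], float)
crude /= crude.sum()
mean_std = float(np.dot(np.arange(13), standardised))
mean_crude = float(np.dot(np.arange(13), crude))
print(f"community mean count: crude {mean_crude:.3f}, standardised {mean_std:.3f}")

# The standardised mean re-weights older/younger strata to the trials' mix;
# with the default age gradient the two differ when trial demography does.
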