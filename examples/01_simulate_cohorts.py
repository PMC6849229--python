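"""Generate synthetic trial and community cohorts with known ground truth.

The generator emulates the setting where trial participants and community
patients share an index condition but differ in multimorbidity: community
mean counts are fixed per condition, per-trial means are log-normal around a
trial-level mean (random-effects heterogeneity), and every true comorbidity
is backed by a matching medication record.
"""

import numpy as np

from trialmorb import simulate_community, simulate_trials, study_config

config = study_config(["asthma", "osteoarthritis"], n_trials=3,
                      participants_per_trial=300, community_n=2000, seed=42)

patients, community_meds, community_truth = simulate_community(config)
participants, trial_meds, trial_truth = simulate_trials(config)

print(f"community patients: {len(patients)}, prescriptions: {len(community_meds)}")
print(f"trial participants: {len(participants)}, medications: {len(trial_meds)}")
for cond in ("asthma", "osteoarthritis"):
    mask = patients["index_condition"] == cond
    counts = [community_truth.counts[p] for p in patients.loc[mask, "person_id"]]
    print(f"{cond}: true community mean count {np.mean(counts):.2f} "
          f"(configured {dict((c.name, c.community_mean) for c in config.conditions)[cond]})")

# Each printed mean is the average number of drug-defined comorbidities per
# patient; it should sit within sampling error of the configured value.
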