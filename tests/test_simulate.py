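"""Synthetic-data generator: determinism, round trip, moment matching."""

import numpy as np
import pandas as pd
import pytest

import trialmorb as tm
from trialmorb.simulate import (
    ConditionConfig,
    GroundTruth,
    SimulationConfig,
    materialise_prescriptions,
    simulate_community,
    simulate_trials,
)


def one_condition(name="asthma", **kw):
    defaults = dict(
        name=name,
        community_mean=1.8,
        trial_log_mean=np.log(0.6),
        trial_sd=0.2,
        n_trials=2,
        participants_per_trial=100,
        community_n=200,
    )
    defaults.update(kw)
    return SimulationConfig(conditions=(ConditionConfig(**defaults),), seed=5)


class TestConfigValidation:
    def test_unknown_condition_label_rejected(self, rules):
        cfg = SimulationConfig(
            conditions=(
                ConditionConfig(
                    name="halitosis", community_mean=1, trial_log_mean=0, trial_sd=0
                ),
            ),
            seed=0,
        )
        with pytest.raises(ValueError, match="unknown index condition"):
            simulate_community(cfg, rules)

    def test_band_probs_must_sum_to_one(self):
        with pytest.raises(ValueError):
            SimulationConfig(
                conditions=(
                    ConditionConfig(
                        name="asthma", community_mean=1, trial_log_mean=0, trial_sd=0
                    ),
                ),
                band_probs=(0.5, 0.2, 0.1, 0.1, 0.1, 0.1),
            )

    def test_negative_trial_sd_rejected(self):
        with pytest.raises(ValueError):
            ConditionConfig(
                name="asthma", community_mean=1, trial_log_mean=0, trial_sd=-0.1
            )


class TestDeterminism:
    def test_community_byte_identical_across_runs(self, small_config, rules):
        a = simulate_community(small_config, rules)
        b = simulate_community(small_config, rules)
        assert a[0].to_csv() == b[0].to_csv()
        assert a[1].to_csv() == b[1].to_csv()
        assert a[2].flags == b[2].flags

    def test_trials_byte_identical_across_runs(self, small_config, rules):
        a = simulate_trials(small_config, rules)
        b = simulate_trials(small_config, rules)
        assert a[0].to_csv() == b[0].to_csv()
        assert a[1].to_csv() == b[1].to_csv()

    def test_different_seed_changes_output(self, small_config, rules):
        other = small_config.model_copy(update={"seed": small_config.seed + 1})
        a = simulate_community(small_config, rules)[0]
        b = simulate_community(other, rules)[0]
        assert a.to_csv() != b.to_csv()


class TestDegenerateCases:
    def test_vanishing_prevalence_gives_zero_counts(self, rules):
        cfg = one_condition(community_mean=1e-12)
        cfg = cfg.model_copy(update={"decoys": False, "name_fraction": 0.0})
        patients, meds, truth = simulate_community(cfg, rules)
        assert all(c == 0 for c in truth.counts.values())
        assert meds.empty  # no comorbidity-backing prescriptions at all

    def test_single_trial_single_participant(self, rules):
        cfg = one_condition(n_trials=1, participants_per_trial=1)
        participants, _, _ = simulate_trials(cfg, rules)
        assert len(participants) == 1
        assert participants["randomisation_date"].notna().all()

    def test_zero_heterogeneity_trial_means_cluster(self, rules):
        """tau = 0: every per-trial mean equals exp(mu) up to sampling noise."""
        mu = np.log(1.2)
        cfg = one_condition(
            trial_log_mean=mu, trial_sd=0.0, n_trials=10, participants_per_trial=400
        )
        _, _, truth = simulate_trials(cfg, rules)
        counts = pd.Series(truth.counts)
        trial_of = counts.index.str.extract(r"(asthma-t\d+)")[0].to_numpy()
        per_trial = counts.groupby(trial_of).mean()
        se = np.sqrt(np.exp(mu) / 400)
        assert (np.abs(per_trial - np.exp(mu)) < 4 * se).all()


class TestMomentMatching:
    def test_community_mean_matches_configuration(self, rules):
        """Empirical mean within 3 SE of the configured mean (Poisson theory)."""
        mean, n = 3.0, 5000
        cfg = one_condition(name="osteoarthritis", community_mean=mean, community_n=n)
        _, _, truth = simulate_community(cfg, rules)
        se = np.sqrt(mean / n)
        assert abs(np.mean(list(truth.counts.values())) - mean) < 3 * se

    def test_trial_grand_mean_matches_lognormal_identity(self, rules):
        """Grand mean across trials targets exp(mu + tau^2/2)."""
        mu, tau, n_trials, n = np.log(1.5), 0.3, 20, 500
        cfg = one_condition(
            trial_log_mean=mu, trial_sd=tau, n_trials=n_trials, participants_per_trial=n
        )
        _, _, truth = simulate_trials(cfg, rules)
        target = np.exp(mu + tau**2 / 2)
        # between-trial variance of the log-normal trial means plus Poisson noise
        var_means = np.exp(2 * mu + tau**2) * (np.exp(tau**2) - 1)
        se = np.sqrt((var_means + target / n) / n_trials)
        assert abs(np.mean(list(truth.counts.values())) - target) < 3 * se

    def test_age_gradient_present(self, rules):
        """Older bands must carry higher mean counts (standardisation signal)."""
        cfg = one_condition(
            name="osteoarthritis", community_mean=2.0, community_n=8000
        )
        patients, _, truth = simulate_community(cfg, rules)
        counts = patients["person_id"].map(truth.counts)
        young = counts[patients["age"] < 40].mean()
        old = counts[patients["age"] >= 70].mean()
        assert old > young


class TestMaterialisePrescriptions:
    def test_empty_flags_give_empty_table(self, rules):
        truth = GroundTruth(flags={"p1": frozenset()}, index_condition={"p1": "asthma"})
        assert materialise_prescriptions(truth, rules).empty

    def test_single_flag_yields_matching_record(self, rules):
        truth = GroundTruth(
            flags={"p1": frozenset({"gout"})}, index_condition={"p1": "asthma"}
        )
        meds = materialise_prescriptions(truth, rules)
        assert len(meds) == 1
        assert meds["atc_code"].iloc[0].startswith("M04A")

    def test_unknown_flag_raises(self, rules):
        truth = GroundTruth(
            flags={"p1": frozenset({"telepathy"})}, index_condition={"p1": "asthma"}
        )
        with pytest.raises(Exception, match="telepathy"):
            materialise_prescriptions(truth, rules)

    def test_round_trip_on_random_flag_sets(self, rules, rng):
        """Classifying the emitted medications recovers 1000 random flag sets."""
        names = np.asarray(rules.names, dtype=object)
        flags = {}
        for i in range(1000):
            k = rng.integers(0, 6)
            flags[f"p{i:04d}"] = frozenset(rng.choice(names, size=k, replace=False))
        truth = GroundTruth(
            flags=flags, index_condition={p: "osteoarthritis" for p in flags}
        )
        meds = materialise_prescriptions(truth, rules, seed=3)
        cohort = pd.DataFrame(
            {
                "person_id": list(flags),
                "index_condition": "osteoarthritis",
                "age": 50,
                "sex": "female",
            }
        )
        out = tm.classify_cohort(meds, cohort, rules)
        for _, row in out.iterrows():
            got = frozenset(n for n in rules.names if row[n])
            want = flags[row["person_id"]] - rules.conflict_set("osteoarthritis")
            assert got == want


class TestEndToEndRoundTrip:
    def test_community_pipeline_recovers_truth(self, community_sim, small_config, rules):
        patients, meds, truth = community_sim
        coded = tm.community_window_filter(tm.assign_atc(meds))
        out = tm.classify_cohort(coded, patients, rules)
        for _, row in out.iterrows():
            got = frozenset(n for n in rules.names if row[n])
            assert got == truth.flags[row["person_id"]]

    def test_trial_pipeline_recovers_truth(self, trial_sim, rules):
        participants, meds, truth = trial_sim
        coded = tm.trial_window_filter(tm.assign_atc(meds), participants)
        out = tm.classify_cohort(coded, participants, rules)
        for _, row in out.iterrows():
            got = frozenset(n for n in rules.names if row[n])
            assert got == truth.flags[row["person_id"]]

    def test_decoys_actually_present(self, trial_sim, community_sim):
        """The generator injects records the filters must remove."""
        _, tmeds, _ = trial_sim
        participants = trial_sim[0]
        rand = participants.set_index("person_id")["randomisation_date"]
        start = pd.to_datetime(tmeds["start_date"], errors="coerce")
        ref = tmeds["person_id"].map(pd.to_datetime(rand))
        assert (start > ref).sum() > 0  # post-randomisation decoys
        assert start.isna().sum() > 0  # missing-date decoys
        _, cmeds, _ = community_sim
        cdates = pd.to_datetime(cmeds["start_date"], errors="coerce")
        assert ((cdates < "2011-01-01") | (cdates > "2011-12-31")).sum() > 0
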