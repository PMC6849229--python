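"""ATC assignment, exposure windows, and the comorbidity classifier."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import trialmorb as tm
from trialmorb.coding import (
    MEDICATION_COLUMNS,
    UNKNOWN,
    assign_atc,
    classify,
    classify_cohort,
    community_window_filter,
    trial_window_filter,
)


def meds(rows):
    return pd.DataFrame(rows, columns=MEDICATION_COLUMNS)


class TestAssignAtc:
    def test_existing_code_passes_through(self):
        out = assign_atc(meds([("p1", "A02BC01", "", "", "2011-01-01")]))
        assert out["atc_code"].tolist() == ["A02BC01"]

    def test_name_and_route_lookup_case_insensitive(self):
        out = assign_atc(meds([("p1", "", "Omeprazole", "ORAL", "2011-01-01")]))
        assert out["atc_code"].tolist() == ["A02BC01"]

    def test_name_without_route_resolves_when_unambiguous(self):
        out = assign_atc(meds([("p1", "", "metformin", "", "2011-01-01")]))
        assert out["atc_code"].tolist() == ["A10BA02"]

    def test_unknown_drug_maps_to_unknown(self):
        out = assign_atc(meds([("p1", "", "xyzzy-unknown-drug", "oral", "2011-01-01")]))
        assert out["atc_code"].tolist() == [UNKNOWN]


class TestTrialWindow:
    RAND = pd.Series(pd.to_datetime(["2015-06-01"]), index=["p1"])

    def kept(self, date):
        m = meds([("p1", "A02BC01", "", "", date)])
        return len(trial_window_filter(m, self.RAND))

    def test_start_on_randomisation_date_kept(self):
        assert self.kept("2015-06-01") == 1

    def test_start_before_randomisation_kept(self):
        assert self.kept("2014-01-15") == 1

    def test_start_day_after_randomisation_dropped(self):
        assert self.kept("2015-06-02") == 0

    def test_missing_start_date_dropped(self):
        assert self.kept(None) == 0

    def test_dropping_missing_date_record_changes_nothing_else(self):
        """Removing an undated record by hand gives the same filtered output."""
        with_missing = meds(
            [("p1", "A02BC01", "", "", "2015-01-01"), ("p1", "A10BA02", "", "", None)]
        )
        without = with_missing.iloc[[0]]
        a = trial_window_filter(with_missing, self.RAND).reset_index(drop=True)
        b = trial_window_filter(without, self.RAND).reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)


class TestCommunityWindow:
    def test_window_boundaries(self):
        m = meds(
            [
                ("p1", "A02BC01", "", "", "2011-01-01"),
                ("p1", "A02BC01", "", "", "2011-12-31"),
                ("p1", "A02BC01", "", "", "2010-12-31"),
                ("p1", "A02BC01", "", "", "2012-01-01"),
            ]
        )
        out = community_window_filter(m)
        assert out["start_date"].tolist() == ["2011-01-01", "2011-12-31"]

    def test_empty_input_empty_output(self):
        assert community_window_filter(meds([])).empty

    def test_widening_window_is_monotone(self, rng):
        dates = [f"{y}-{m:02d}-15" for y in (2010, 2011, 2012) for m in (1, 6, 12)]
        m = meds([("p1", "A02BC01", "", "", d) for d in rng.choice(dates, 10)])
        narrow = community_window_filter(m)
        wide = community_window_filter(m, ("2010-01-01", "2012-12-31"))
        assert set(narrow.index) <= set(wide.index)

    def test_inverted_window_rejected(self):
        with pytest.raises(ValueError):
            community_window_filter(meds([]), ("2012-01-01", "2011-01-01"))


class TestClassify:
    def test_no_records_empty_profile(self, rules):
        prof = classify(meds([]), "asthma", rules, person_id="p1")
        assert prof.flags == frozenset() and prof.count == 0

    def test_index_condition_suppression(self, rules):
        """An asthma trial participant on inhaled therapy is not comorbid for asthma/COPD."""
        m = meds([("p1", "R03AC02", "", "", "2011-05-01")])
        asthma = classify(m, "asthma", rules)
        other = classify(m, "osteoarthritis", rules)
        assert "asthma_copd" not in asthma.flags and asthma.count == 0
        assert "asthma_copd" in other.flags and other.count == 1

    def test_unknown_codes_contribute_nothing(self, rules):
        m = meds([("p1", UNKNOWN, "", "", "2011-05-01")])
        assert classify(m, "asthma", rules).count == 0

    def test_unknown_index_condition_raises(self, rules):
        with pytest.raises(KeyError):
            classify(meds([]), "not_a_condition", rules)

    def test_count_bounded_by_definable_comorbidities(self, rules):
        all_codes = [rules.representative_code(n) for n in rules.names]
        m = meds([("p1", c, "", "", "2011-05-01") for c in all_codes])
        prof = classify(m, "asthma", rules)
        assert prof.count == 20  # asthma suppresses asthma_copd
        assert classify(m, "atrial_fibrillation", rules).count == 19  # two conflicts


def brute_force_flags(codes, index_condition, rules):
    """Independent oracle: test every (code, prefix) pair character by character."""

    def extends(code, prefix):
        if len(code) < len(prefix):
            return False
        return all(code[i] == prefix[i] for i in range(len(prefix)))

    flags = set()
    for rule in rules.rules:
        for code in codes:
            if code == UNKNOWN:
                continue
            inc = any(extends(code, p) for p in rule.include)
            exc = any(extends(code, p) for p in rule.exclude)
            if inc and not exc:
                flags.add(rule.name)
                break
    return frozenset(flags) - rules.conflict_set(index_condition)


class TestClassifierOracle:
    def test_matches_brute_force_on_random_inputs(self, rules, rng):
        """500 random medication sets: classifier equals naive prefix matching."""
        alphabet = list("ABCDGHJLMNRSV")
        conditions = sorted(rules.index_conditions)
        for trial in range(500):
            n_codes = rng.integers(0, 8)
            codes = [
                f"{rng.choice(alphabet)}{rng.integers(10):01d}{rng.integers(10):01d}"
                f"{rng.choice(list('ABCDE'))}{rng.choice(list('ABCDE'))}"
                f"{rng.integers(10):01d}{rng.integers(10):01d}"[: rng.choice([3, 4, 5, 7])]
                for _ in range(n_codes)
            ]
            # mix in real rule-matching codes so hits actually occur
            if rng.random() < 0.7 and n_codes:
                codes[0] = rules.representative_code(str(rng.choice(rules.names)))
            cond = str(rng.choice(conditions))
            m = meds([("p1", c, "", "", "2011-06-01") for c in codes])
            assert classify(m, cond, rules).flags == brute_force_flags(codes, cond, rules)

    @settings(max_examples=50, deadline=None)
    @given(
        codes=st.lists(
            st.from_regex(r"[A-Z]\d\d[A-Z][A-Z]\d\d", fullmatch=True), max_size=6
        ),
        cond=st.sampled_from(sorted(tm.default_rule_table().index_conditions)),
    )
    def test_property_oracle_equivalence(self, codes, cond):
        rules = tm.default_rule_table()
        m = meds([("p1", c, "", "", "2011-06-01") for c in codes])
        assert classify(m, cond, rules).flags == brute_force_flags(codes, cond, rules)


class TestClassifierProperties:
    def test_duplicates_are_idempotent(self, rules):
        m = meds([("p1", "A02BC01", "", "", "2011-05-01")] * 5)
        one = meds([("p1", "A02BC01", "", "", "2011-05-01")])
        assert classify(m, "asthma", rules).flags == classify(one, "asthma", rules).flags

    def test_adding_a_record_never_removes_flags(self, rules, rng):
        base_codes = ["A02BC01", "R03AC02"]
        m = meds([("p1", c, "", "", "2011-05-01") for c in base_codes])
        before = classify(m, "osteoarthritis", rules).flags
        extra = rules.representative_code(str(rng.choice(rules.names)))
        m2 = pd.concat([m, meds([("p1", extra, "", "", "2011-05-01")])])
        after = classify(m2, "osteoarthritis", rules).flags
        assert before <= after


class TestClassifyCohort:
    def test_matches_per_person_classifier(self, rules, rng):
        conditions = sorted(rules.index_conditions)
        people = []
        rows = []
        for i in range(50):
            pid = f"p{i}"
            cond = str(rng.choice(conditions))
            people.append((pid, cond, 50, "female"))
            for _ in range(rng.integers(0, 4)):
                code = rules.representative_code(str(rng.choice(rules.names)))
                rows.append((pid, code, "", "", "2011-06-01"))
        persons = pd.DataFrame(people, columns=["person_id", "index_condition", "age", "sex"])
        m = meds(rows)
        cohort = classify_cohort(m, persons, rules)
        for _, row in cohort.iterrows():
            single = classify(
                m[m["person_id"] == row["person_id"]], row["index_condition"], rules
            )
            got = frozenset(n for n in rules.names if row[n])
            assert got == single.flags
            assert row["count"] == single.count
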