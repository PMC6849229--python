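"""Classify drug-defined comorbidities from medication records.

The ascertainment pipeline mirrors how concomitant-medication data are
handled when individual-level trial data and primary-care prescribing data
are compared:

1. medications carry an ATC code directly, or a free-text drug name (often
   with a route) that is mapped to ATC through a lookup table
   (:func:`assign_atc`; unmatched names become ``UNKNOWN``);
2. an exposure window is applied — for trial participants any drug started
   on or before the randomisation date (:func:`trial_window_filter`), for
   community patients any drug prescribed during the observation year
   (:func:`community_window_filter`, default calendar 2011);
3. the windowed codes are matched against the comorbidity rule table and
   comorbidities conflicting with the person's index condition are
   suppressed (:func:`classify`); the comorbidity count is the number of
   distinct flagged comorbidities, never including the index condition.

Medication tables are plain :class:`pandas.DataFrame` objects with columns
``person_id, atc_code, drug_name, route, start_date`` (missing values
allowed where the docstrings say so).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from os import PathLike

import numpy as np
import pandas as pd

from .rules import ComorbidityRuleTable, default_rule_table, normalise_atc

__all__ = [
    "UNKNOWN",
    "MEDICATION_COLUMNS",
    "ComorbidityProfile",
    "load_atc_lookup",
    "default_atc_lookup",
    "assign_atc",
    "trial_window_filter",
    "community_window_filter",
    "classify",
    "classify_cohort",
]

logger = logging.getLogger(__name__)

#: Sentinel ATC value for drug names the lookup cannot resolve.
UNKNOWN = "UNKNOWN"

MEDICATION_COLUMNS = ["person_id", "atc_code", "drug_name", "route", "start_date"]

COMMUNITY_WINDOW = (pd.Timestamp("2011-01-01"), pd.Timestamp("2011-12-31"))


@dataclass(frozen=True)
class ComorbidityProfile:
    """Flagged comorbidities and their count for one person."""

    person_id: str
    index_condition: str
    flags: frozenset[str]

    @property
    def count(self) -> int:
        return len(self.flags)


def load_atc_lookup(path: str | PathLike) -> dict[tuple[str, str], str]:
    """Read a drug-name → ATC lookup CSV (drug_name, route, atc_code).

    Keys are lower-cased ``(name, route)`` pairs; a second entry with route
    ``""`` is stored so a record with a missing route still resolves when the
    name is unambiguous in the table.
    """
    df = pd.read_csv(path, dtype=str).fillna("")
    lookup: dict[tuple[str, str], str] = {}
    by_name: dict[str, set[str]] = {}
    for _, row in df.iterrows():
        name = row["drug_name"].strip().lower()
        route = row["route"].strip().lower()
        code = normalise_atc(row["atc_code"])
        lookup[(name, route)] = code
        by_name.setdefault(name, set()).add(code)
    for name, codes in by_name.items():
        if len(codes) == 1:
            lookup.setdefault((name, ""), next(iter(codes)))
    return lookup


def default_atc_lookup() -> dict[tuple[str, str], str]:
    """The small shipped name→ATC fixture (common representative drugs)."""
    with resources.as_file(
        resources.files("trialmorb.data") / "atc_name_lookup.csv"
    ) as p:
        return load_atc_lookup(p)


def assign_atc(
    medications: pd.DataFrame,
    lookup: dict[tuple[str, str], str] | None = None,
) -> pd.DataFrame:
    """Fill missing ATC codes from drug name (+ route); unmatched → ``UNKNOWN``.

    Records already carrying an ATC code pass through unchanged (after
    normalisation to upper case).  Matching on name and route is
    case-insensitive.  The number of unresolved names is logged.
    """
    if lookup is None:
        lookup = default_atc_lookup()
    meds = medications.copy()
    codes = meds["atc_code"].astype("string")
    has_code = (codes.notna() & (codes.str.strip() != "")).to_numpy()
    out = np.where(has_code, codes.str.strip().str.upper().fillna(""), "").astype(object)

    need = ~has_code
    if need.any():
        names = meds.loc[need, "drug_name"].astype("string").str.strip().str.lower()
        routes = (
            meds.loc[need, "route"].astype("string").str.strip().str.lower().fillna("")
            if "route" in meds
            else pd.Series("", index=names.index)
        )
        mapped = [
            lookup.get((n, r), lookup.get((n, ""), UNKNOWN)) if pd.notna(n) else UNKNOWN
            for n, r in zip(names, routes)
        ]
        out[np.flatnonzero(need)] = mapped
        n_unknown = sum(m == UNKNOWN for m in mapped)
        if n_unknown:
            logger.info(
                "assign_atc: %d of %d name-based records unresolved (UNKNOWN)",
                n_unknown,
                int(need.sum()),
            )
    meds["atc_code"] = pd.Series(out, index=meds.index, dtype=str)
    return meds


def _as_datetime(s: pd.Series) -> pd.Series:
    return pd.to_datetime(s, errors="coerce")


def trial_window_filter(
    medications: pd.DataFrame,
    randomisation_dates: pd.Series | pd.DataFrame,
) -> pd.DataFrame:
    """Keep concomitant medications started on or before randomisation.

    ``randomisation_dates`` maps person_id → date (a Series indexed by
    person_id, or a participants table with ``person_id`` and
    ``randomisation_date`` columns).  Records with a missing start date
    cannot be confirmed as pre-randomisation exposure and are dropped; drop
    totals are logged.
    """
    if isinstance(randomisation_dates, pd.DataFrame):
        randomisation_dates = randomisation_dates.set_index("person_id")[
            "randomisation_date"
        ]
    rand = _as_datetime(randomisation_dates)
    if rand.isna().any():
        missing = rand.index[rand.isna()].tolist()
        raise ValueError(f"missing randomisation date for: {missing[:5]}")
    start = _as_datetime(medications["start_date"])
    ref = medications["person_id"].map(rand)
    keep = start.notna() & ref.notna() & (start <= ref)
    n_missing = int(start.isna().sum())
    n_post = int((start.notna() & ref.notna() & (start > ref)).sum())
    logger.info(
        "trial_window_filter: kept=%d dropped_post_randomisation=%d dropped_missing_date=%d",
        int(keep.sum()),
        n_post,
        n_missing,
    )
    return medications.loc[keep].copy()


def community_window_filter(
    medications: pd.DataFrame,
    window: tuple[pd.Timestamp, pd.Timestamp] = COMMUNITY_WINDOW,
) -> pd.DataFrame:
    """Keep prescriptions dated inside the closed observation window."""
    lo, hi = (pd.Timestamp(window[0]), pd.Timestamp(window[1]))
    if lo > hi:
        raise ValueError("window start after window end")
    start = _as_datetime(medications["start_date"])
    keep = start.notna() & (start >= lo) & (start <= hi)
    logger.info(
        "community_window_filter: kept=%d dropped=%d",
        int(keep.sum()),
        int((~keep).sum()),
    )
    return medications.loc[keep].copy()


def classify(
    records: pd.DataFrame,
    index_condition: str,
    rules: ComorbidityRuleTable | None = None,
    person_id: str = "",
) -> ComorbidityProfile:
    """Comorbidity profile for one person's window-filtered medications.

    A comorbidity is flagged when at least one record's ATC code extends an
    include prefix and no exclude prefix of its rule; comorbidities in the
    index condition's conflict set are never flagged (the condition under
    treatment is not its own comorbidity).  ``UNKNOWN`` codes contribute
    nothing.  Raises ``KeyError`` for an index condition outside the
    conflict-map vocabulary.
    """
    if rules is None:
        rules = default_rule_table()
    suppressed = rules.conflict_set(index_condition)
    flags: set[str] = set()
    if len(records):
        codes = {
            normalise_atc(c)
            for c in records["atc_code"].dropna().astype(str)
            if c and c != UNKNOWN
        }
        for code in codes:
            flags |= rules.classify_code(code)
    if not person_id and len(records):
        ids = records["person_id"].unique()
        person_id = str(ids[0]) if len(ids) == 1 else ""
    return ComorbidityProfile(
        person_id=person_id,
        index_condition=index_condition,
        flags=frozenset(flags - suppressed),
    )


def classify_cohort(
    medications: pd.DataFrame,
    persons: pd.DataFrame,
    rules: ComorbidityRuleTable | None = None,
) -> pd.DataFrame:
    """Vectorised classification for a whole cohort.

    ``persons`` needs ``person_id`` and ``index_condition`` columns (extra
    columns such as age/sex/trial_id are carried through).  Returns one row
    per person with a 0/1 column per comorbidity and a ``count`` column;
    people without medications get all-zero rows.
    """
    if rules is None:
        rules = default_rule_table()
    for cond in persons["index_condition"].unique():
        rules.conflict_set(cond)  # raises on unknown vocabulary

    out = persons.copy().reset_index(drop=True)
    codes = medications["atc_code"].astype(str).str.strip().str.upper()
    flag_frames = {}
    for rule in rules.rules:
        hit = np.zeros(len(medications), dtype=bool)
        for p in rule.include:
            hit |= codes.str.startswith(p).to_numpy()
        for p in rule.exclude:
            hit &= ~codes.str.startswith(p).to_numpy()
        flagged = set(medications.loc[hit, "person_id"])
        flag_frames[rule.name] = out["person_id"].isin(flagged).astype(int)
    flags = pd.DataFrame(flag_frames)
    # index-condition suppression
    for cond in out["index_condition"].unique():
        supp = rules.conflict_set(cond)
        mask = (out["index_condition"] == cond).to_numpy()
        for name in supp:
            flags.loc[mask, name] = 0
    out = pd.concat([out, flags], axis=1)
    out["count"] = flags.sum(axis=1)
    return out
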