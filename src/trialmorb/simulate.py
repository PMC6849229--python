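"""Synthetic trial and community cohorts with known comorbidity ground truth.

Restricted safe-haven data (trial repositories, national primary-care
databanks) cannot be redistributed, so end-to-end testing of the
classification → aggregation → inference pipeline runs on synthetic cohorts
whose true comorbidity flags are known by construction.

The generating model mirrors the downstream analysis assumptions:

* a person's comorbidity count is Poisson with a rate that varies
  multiplicatively by age band and sex (so age–sex standardisation has a
  real signal to remove), normalised so the marginal mean equals the
  configured mean;
* trial heterogeneity enters on the log scale — each trial's mean count is
  ``exp(Normal(mu, tau))``, matching the log-link random-effects model used
  for inference; the community mean is a fixed configured value;
* every true comorbidity flag is backed by at least one medication record
  whose ATC code unambiguously matches that comorbidity's rule (community
  prescriptions dated inside the observation year; trial medications started
  on or before randomisation), so re-classifying the emitted medications
  recovers the flags exactly;
* optional decoys exercise the filters: medications with codes matching no
  comorbidity, out-of-window or post-randomisation medications that *do*
  match rules, records with missing start dates, and a fraction of records
  carrying a drug name instead of an ATC code (resolved via the name→ATC
  lookup).

Everything is deterministic given the configuration seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from .coding import MEDICATION_COLUMNS, default_atc_lookup
from .rules import ComorbidityRuleTable, RuleTableError, default_rule_table

__all__ = [
    "ConditionConfig",
    "SimulationConfig",
    "GroundTruth",
    "simulate_community",
    "simulate_trials",
    "materialise_prescriptions",
    "study_config",
]

#: Full ATC codes that match no rule in the default table (decoy drugs).
DECOY_CODES = ("V03AB01", "J01CA04", "D08AC02")

DEFAULT_AGE_BANDS = ((18, 40), (40, 50), (50, 60), (60, 70), (70, 80), (80, 105))
DEFAULT_BAND_PROBS = (0.20, 0.20, 0.20, 0.20, 0.12, 0.08)
DEFAULT_BAND_MULTIPLIERS = (0.55, 0.75, 0.95, 1.20, 1.50, 1.80)


class ConditionConfig(BaseModel):
    """Generating parameters for one index condition."""

    model_config = ConfigDict(frozen=True)

    name: str
    community_mean: float = Field(gt=0)
    trial_log_mean: float
    trial_sd: float = Field(ge=0, description="between-trial SD on the log scale")
    n_trials: int = Field(ge=1, default=5)
    participants_per_trial: int = Field(ge=1, default=500)
    community_n: int = Field(ge=1, default=5000)


class SimulationConfig(BaseModel):
    """Full study configuration for the synthetic-data generator.

    Age bands are closed-open ``[lo, hi)`` intervals partitioning the adult
    age range; ``band_multipliers`` and ``sex_multipliers`` scale the Poisson
    rate per stratum (internally normalised so the marginal mean count stays
    at the configured value).  ``decoys`` switches the filter-exercising
    noise records on/off; ``name_fraction`` is the share of comorbidity
    medications emitted as drug names rather than ATC codes.
    """

    model_config = ConfigDict(frozen=True)

    conditions: tuple[ConditionConfig, ...] = Field(min_length=1)
    age_bands: tuple[tuple[int, int], ...] = DEFAULT_AGE_BANDS
    band_probs: tuple[float, ...] = DEFAULT_BAND_PROBS
    band_multipliers: tuple[float, ...] = DEFAULT_BAND_MULTIPLIERS
    sex_multipliers: dict[str, float] = Field(
        default_factory=lambda: {"female": 1.0, "male": 1.1}
    )
    decoys: bool = True
    name_fraction: float = Field(ge=0, le=1, default=0.10)
    seed: int = 0

    @field_validator("band_probs")
    @classmethod
    def _probs_sum_to_one(cls, v):
        if abs(sum(v) - 1.0) > 1e-9:
            raise ValueError("band_probs must sum to 1")
        if any(p < 0 for p in v):
            raise ValueError("band_probs must be non-negative")
        return v

    @field_validator("band_multipliers")
    @classmethod
    def _multipliers_positive(cls, v):
        if any(m <= 0 for m in v):
            raise ValueError("band_multipliers must be positive")
        return v

    @field_validator("sex_multipliers")
    @classmethod
    def _sex_multipliers_valid(cls, v):
        if set(v) != {"female", "male"} or any(m <= 0 for m in v.values()):
            raise ValueError("sex_multipliers needs positive female/male entries")
        return v

    @model_validator(mode="after")
    def _bands_consistent(self):
        if not (
            len(self.age_bands) == len(self.band_probs) == len(self.band_multipliers)
        ):
            raise ValueError("age_bands, band_probs, band_multipliers lengths differ")
        for (lo, hi), (lo2, _hi2) in zip(self.age_bands, self.age_bands[1:]):
            if hi != lo2:
                raise ValueError("age bands must be contiguous and ordered")
        if any(lo >= hi for lo, hi in self.age_bands):
            raise ValueError("age band lower bound must be below upper bound")
        names = [c.name for c in self.conditions]
        if len(set(names)) != len(names):
            raise ValueError("duplicate condition names")
        return self

    @classmethod
    def from_file(cls, path) -> "SimulationConfig":
        """Read a config from YAML or JSON."""
        import yaml

        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh))


@dataclass
class GroundTruth:
    """True comorbidity flags per person (post index-condition suppression)."""

    flags: dict[str, frozenset[str]] = field(default_factory=dict)
    index_condition: dict[str, str] = field(default_factory=dict)

    @property
    def counts(self) -> dict[str, int]:
        return {pid: len(f) for pid, f in self.flags.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "person_id": pid,
                "index_condition": self.index_condition[pid],
                "count": len(fl),
                "flags": ";".join(sorted(fl)),
            }
            for pid, fl in self.flags.items()
        ]
        return pd.DataFrame(rows, columns=["person_id", "index_condition", "count", "flags"])


def _check_conditions(config: SimulationConfig, rules: ComorbidityRuleTable) -> None:
    known = rules.index_conditions
    bad = [c.name for c in config.conditions if c.name not in known]
    if bad:
        raise ValueError(f"unknown index condition labels: {bad}; known: {sorted(known)}")


def _expected_multiplier(config: SimulationConfig) -> float:
    band = float(np.dot(config.band_probs, config.band_multipliers))
    sexes = config.sex_multipliers
    return band * (0.5 * sexes["female"] + 0.5 * sexes["male"])


def _draw_people(
    rng: np.random.Generator, config: SimulationConfig, n: int, mean: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw (age, sex, poisson rate) for n people with marginal mean ``mean``."""
    bands = np.asarray(config.age_bands)
    b = rng.choice(len(bands), size=n, p=np.asarray(config.band_probs))
    ages = rng.integers(bands[b, 0], bands[b, 1])
    sex = np.where(rng.random(n) < 0.5, "female", "male")
    mult = np.asarray(config.band_multipliers)[b] * np.where(
        sex == "female",
        config.sex_multipliers["female"],
        config.sex_multipliers["male"],
    )
    rates = mean * mult / _expected_multiplier(config)
    return ages, sex, rates


def _draw_flags(
    rng: np.random.Generator,
    rates: np.ndarray,
    allowed: list[str],
) -> list[frozenset[str]]:
    """Poisson counts (capped at the allowed-set size) mapped to flag sets."""
    counts = np.minimum(rng.poisson(rates), len(allowed))
    allowed_arr = np.asarray(allowed, dtype=object)
    return [
        frozenset(rng.choice(allowed_arr, size=c, replace=False)) if c else frozenset()
        for c in counts
    ]


def _named_drugs(rules: ComorbidityRuleTable) -> dict[str, tuple[str, str, str]]:
    """comorbidity → (drug_name, route, code) pairs resolvable by the shipped lookup."""
    out: dict[str, tuple[str, str, str]] = {}
    for (name, route), code in sorted(default_atc_lookup().items()):
        if not route:
            continue
        hits = rules.classify_code(code)
        if len(hits) == 1:
            out.setdefault(next(iter(hits)), (name, route, code))
    return out


def materialise_prescriptions(
    truth: GroundTruth,
    rules: ComorbidityRuleTable | None = None,
    *,
    seed: int = 0,
    date_range: tuple[str, str] = ("2011-01-01", "2011-12-31"),
    name_fraction: float = 0.0,
    decoys: bool = False,
) -> pd.DataFrame:
    """Emit one medication record per true comorbidity flag.

    Each record's ATC code matches exactly the flag's rule (and no other
    rule), so classifying the output with the same rule table recovers the
    flags — the round-trip property the generator guarantees.  With
    ``name_fraction`` > 0 a share of records carries a resolvable drug name
    instead of a code; with ``decoys`` non-matching medications are added.
    Raises :class:`RuleTableError` if a flag has no unambiguous code.
    """
    if rules is None:
        rules = default_rule_table()
    rng = np.random.default_rng(seed)
    rep = {name: rules.representative_code(name) for name in rules.names}
    named = _named_drugs(rules)
    lo, hi = pd.Timestamp(date_range[0]), pd.Timestamp(date_range[1])
    span = (hi - lo).days
    rows: list[tuple] = []
    for pid in sorted(truth.flags):
        for flag in sorted(truth.flags[pid]):
            if flag not in rep:
                raise RuleTableError(f"flag {flag!r} has no rule with an ATC prefix")
            date = (lo + pd.Timedelta(days=int(rng.integers(0, span + 1)))).date()
            if flag in named and rng.random() < name_fraction:
                drug, route, _ = named[flag]
                rows.append((pid, "", drug, route, date.isoformat()))
            else:
                rows.append((pid, rep[flag], "", "", date.isoformat()))
        if decoys and rng.random() < 0.5:
            code = DECOY_CODES[int(rng.integers(len(DECOY_CODES)))]
            date = (lo + pd.Timedelta(days=int(rng.integers(0, span + 1)))).date()
            rows.append((pid, code, "", "", date.isoformat()))
    return pd.DataFrame(rows, columns=MEDICATION_COLUMNS)


def simulate_community(
    config: SimulationConfig,
    rules: ComorbidityRuleTable | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate the community cohort: patients, 2011 prescriptions, ground truth.

    Patients get an age, sex and index-condition label; every true flag is
    backed by a prescription dated inside 2011.  With decoys on, extra
    records are added that the community window filter or the rule matcher
    must reject: out-of-window prescriptions whose codes *do* match rules,
    and in-window prescriptions matching no rule.
    """
    if rules is None:
        rules = default_rule_table()
    _check_conditions(config, rules)
    ss = np.random.SeedSequence([config.seed, 1])
    patients_rows = []
    truth = GroundTruth()
    med_frames = []
    for cond, child in zip(config.conditions, ss.spawn(len(config.conditions))):
        rng = np.random.default_rng(child)
        allowed = rules.allowed_comorbidities(cond.name)
        ages, sex, rates = _draw_people(rng, config, cond.community_n, cond.community_mean)
        flags = _draw_flags(rng, rates, allowed)
        pids = [f"{cond.name}-c{i:06d}" for i in range(cond.community_n)]
        for pid, a, s, fl in zip(pids, ages, sex, flags):
            patients_rows.append((pid, cond.name, int(a), s))
            truth.flags[pid] = fl
            truth.index_condition[pid] = cond.name
        part = GroundTruth(
            flags={p: truth.flags[p] for p in pids},
            index_condition={p: cond.name for p in pids},
        )
        meds = materialise_prescriptions(
            part,
            rules,
            seed=int(rng.integers(2**31)),
            name_fraction=config.name_fraction,
            decoys=config.decoys,
        )
        if config.decoys:
            meds = pd.concat(
                [meds, _community_decoys(rng, pids, rules)], ignore_index=True
            )
        med_frames.append(meds)
    patients = pd.DataFrame(
        patients_rows, columns=["person_id", "index_condition", "age", "sex"]
    )
    medications = pd.concat(med_frames, ignore_index=True)
    return patients, medications, truth


def _community_decoys(
    rng: np.random.Generator, pids: list[str], rules: ComorbidityRuleTable
) -> pd.DataFrame:
    """Out-of-window prescriptions with rule-matching codes (must be filtered)."""
    rep = [rules.representative_code(n) for n in rules.names]
    rows = []
    for pid in pids:
        if rng.random() < 0.3:
            code = rep[int(rng.integers(len(rep)))]
            when = "2010" if rng.random() < 0.5 else "2012"
            date = f"{when}-{int(rng.integers(1, 13)):02d}-{int(rng.integers(1, 29)):02d}"
            rows.append((pid, code, "", "", date))
    return pd.DataFrame(rows, columns=MEDICATION_COLUMNS)


def simulate_trials(
    config: SimulationConfig,
    rules: ComorbidityRuleTable | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate trial participants, concomitant medications and ground truth.

    Per-trial mean counts are log-normal around ``trial_log_mean`` with SD
    ``trial_sd`` (the random-effects structure the inference module fits).
    Every participant has a randomisation date; true-flag medications start
    on or before it.  With decoys on, post-randomisation medications with
    rule-matching codes and records with missing start dates are injected to
    exercise the trial exposure filter.
    """
    if rules is None:
        rules = default_rule_table()
    _check_conditions(config, rules)
    ss = np.random.SeedSequence([config.seed, 2])
    rows = []
    truth = GroundTruth()
    med_frames = []
    for cond, child in zip(config.conditions, ss.spawn(len(config.conditions))):
        rng = np.random.default_rng(child)
        allowed = rules.allowed_comorbidities(cond.name)
        rep = [rules.representative_code(n) for n in rules.names]
        trial_means = np.exp(
            rng.normal(cond.trial_log_mean, cond.trial_sd, size=cond.n_trials)
        )
        for t in range(cond.n_trials):
            trial_id = f"{cond.name}-t{t:02d}"
            rand_date = pd.Timestamp("2015-03-01") + pd.Timedelta(days=30 * t)
            n = cond.participants_per_trial
            ages, sex, rates = _draw_people(rng, config, n, float(trial_means[t]))
            flags = _draw_flags(rng, rates, allowed)
            pids = [f"{trial_id}-p{i:05d}" for i in range(n)]
            med_rows = []
            for pid, a, s, fl in zip(pids, ages, sex, flags):
                rows.append(
                    (pid, trial_id, cond.name, int(a), s, rand_date.date().isoformat())
                )
                truth.flags[pid] = fl
                truth.index_condition[pid] = cond.name
                for flag in sorted(fl):
                    start = rand_date - pd.Timedelta(days=int(rng.integers(1, 366)))
                    med_rows.append(
                        (pid, rules.representative_code(flag), "", "",
                         start.date().isoformat())
                    )
                if config.decoys:
                    if rng.random() < 0.3:  # post-randomisation, must be dropped
                        code = rep[int(rng.integers(len(rep)))]
                        start = rand_date + pd.Timedelta(days=int(rng.integers(1, 201)))
                        med_rows.append((pid, code, "", "", start.date().isoformat()))
                    if rng.random() < 0.1:  # missing start date, must be dropped
                        code = rep[int(rng.integers(len(rep)))]
                        med_rows.append((pid, code, "", "", ""))
                    if rng.random() < 0.3:  # pre-randomisation non-matching drug
                        code = DECOY_CODES[int(rng.integers(len(DECOY_CODES)))]
                        start = rand_date - pd.Timedelta(days=int(rng.integers(1, 366)))
                        med_rows.append((pid, code, "", "", start.date().isoformat()))
            med_frames.append(pd.DataFrame(med_rows, columns=MEDICATION_COLUMNS))
    participants = pd.DataFrame(
        rows,
        columns=["person_id", "trial_id", "index_condition", "age", "sex",
                 "randomisation_date"],
    )
    medications = pd.concat(med_frames, ignore_index=True)
    return participants, medications, truth


def study_config(
    conditions: list[str] | None = None,
    *,
    n_trials: int = 5,
    participants_per_trial: int = 500,
    community_n: int = 5000,
    trial_sd: float = 0.3,
    seed: int = 0,
    community_trial_ratio: float | None = None,
) -> SimulationConfig:
    """Configuration seeded from published per-condition summary estimates.

    Community means and trial log-means default to published point estimates
    for the requested index conditions (all 22 when ``conditions`` is None).
    ``community_trial_ratio`` overrides the trial mean as
    ``community_mean / ratio`` — handy for generating data with a known
    ratio ground truth.
    """
    with resources.as_file(
        resources.files("trialmorb.data") / "published_count_summaries.csv"
    ) as p:
        pub = pd.read_csv(p).set_index("condition")
    if conditions is None:
        conditions = list(pub.index)
    unknown = [c for c in conditions if c not in pub.index]
    if unknown:
        raise ValueError(f"no published summary for: {unknown}")
    cfgs = []
    for c in conditions:
        community_mean = float(pub.loc[c, "community_mean"])
        trial_mean = (
            community_mean / community_trial_ratio
            if community_trial_ratio
            else float(pub.loc[c, "trial_mean"])
        )
        cfgs.append(
            ConditionConfig(
                name=c,
                community_mean=community_mean,
                trial_log_mean=float(np.log(trial_mean)),
                trial_sd=trial_sd,
                n_trials=n_trials,
                participants_per_trial=participants_per_trial,
                community_n=community_n,
            )
        )
    return SimulationConfig(conditions=tuple(cfgs), seed=seed)
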