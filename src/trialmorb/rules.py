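"""Rule tables for medication-based comorbidity ascertainment.

Comorbidities are defined by WHO ATC code prefixes: a medication counts
towards a comorbidity when its ATC code *extends* one of the rule's include
prefixes (the ATC scheme is hierarchical, so a 4-character prefix such as
``A02B`` captures the whole drug class) and extends none of its exclude
prefixes.  Exclude prefixes express drug-level carve-outs — for example
amitriptyline (``N06AA09``) is widely prescribed for chronic pain and is
therefore removed from the affective-disorders definition.

Each index condition may *suppress* comorbidities judged to be the same
disease as the indication itself (an asthma trial participant on inhaled
bronchodilators is not "comorbid" for asthma/COPD); the conflict map encodes
this and classification drops suppressed names before counting.

The shipped default table names 21 drug-defined comorbidities and is a
documented reconstruction of a published medication-based definition set:
representative ATC drug-class prefixes chosen so that no include prefix of
one comorbidity extends that of another.  It is package data and fully
user-replaceable via :func:`load_rule_table`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from os import PathLike
from typing import Iterable, Mapping

__all__ = [
    "ComorbidityRule",
    "ComorbidityRuleTable",
    "RuleTableError",
    "normalise_atc",
    "is_valid_atc_prefix",
    "load_rule_table",
    "load_conflict_map",
    "default_rule_table",
]

# ATC level lengths: anatomical group (1), therapeutic subgroup (3),
# pharmacological subgroup (4), chemical subgroup (5), substance (7).
_ATC_LEVEL_RE = {
    1: re.compile(r"^[A-Z]$"),
    3: re.compile(r"^[A-Z]\d\d$"),
    4: re.compile(r"^[A-Z]\d\d[A-Z]$"),
    5: re.compile(r"^[A-Z]\d\d[A-Z][A-Z]$"),
    7: re.compile(r"^[A-Z]\d\d[A-Z][A-Z]\d\d$"),
}


class RuleTableError(ValueError):
    """Raised when a rule table or conflict map fails validation."""


def normalise_atc(code: str) -> str:
    """Upper-case and strip an ATC code or prefix (no validity check)."""
    return str(code).strip().upper()


def is_valid_atc_prefix(prefix: str) -> bool:
    """True when ``prefix`` is a well-formed ATC string at any level."""
    pat = _ATC_LEVEL_RE.get(len(prefix))
    return bool(pat and pat.match(prefix))


@dataclass(frozen=True)
class ComorbidityRule:
    """ATC include/exclude prefixes defining one comorbidity."""

    name: str
    include: tuple[str, ...]
    exclude: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.include:
            raise RuleTableError(f"{self.name!r}: no include prefix")
        for p in self.include + self.exclude:
            if not is_valid_atc_prefix(p):
                raise RuleTableError(f"{self.name!r}: malformed ATC prefix {p!r}")
        overlap = set(self.include) & set(self.exclude)
        if overlap:
            raise RuleTableError(
                f"{self.name!r}: prefixes both included and excluded: {sorted(overlap)}"
            )

    def matches(self, code: str) -> bool:
        """Does an ATC code extend an include prefix and no exclude prefix?"""
        if any(code.startswith(p) for p in self.exclude):
            return False
        return any(code.startswith(p) for p in self.include)


@dataclass
class ComorbidityRuleTable:
    """A set of comorbidity rules plus the index-condition conflict map."""

    rules: list[ComorbidityRule]
    conflicts: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [r.name for r in self.rules]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise RuleTableError(f"duplicate comorbidity names: {sorted(dupes)}")
        if not names:
            raise RuleTableError("rule table is empty")
        known = set(names)
        for cond, supp in self.conflicts.items():
            bad = supp - known
            if bad:
                raise RuleTableError(
                    f"conflict map for {cond!r} names unknown comorbidities: {sorted(bad)}"
                )

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.rules]

    @property
    def index_conditions(self) -> frozenset[str]:
        """Vocabulary of index-condition labels the conflict map knows."""
        return frozenset(self.conflicts)

    def rule(self, name: str) -> ComorbidityRule:
        for r in self.rules:
            if r.name == name:
                return r
        raise KeyError(name)

    def conflict_set(self, index_condition: str) -> frozenset[str]:
        """Comorbidities not defined for this index condition."""
        if index_condition not in self.conflicts:
            raise KeyError(
                f"unknown index condition {index_condition!r}; known: "
                f"{sorted(self.conflicts)}"
            )
        return self.conflicts[index_condition]

    def allowed_comorbidities(self, index_condition: str) -> list[str]:
        supp = self.conflict_set(index_condition)
        return [n for n in self.names if n not in supp]

    def classify_code(self, code: str) -> frozenset[str]:
        """All comorbidity names whose rule a single ATC code satisfies."""
        return frozenset(r.name for r in self.rules if r.matches(code))

    def representative_code(self, name: str) -> str:
        """A full 7-character ATC code matching ``name`` and nothing else.

        Used by the synthetic-data generator; raises :class:`RuleTableError`
        when the table's prefixes are so entangled that no such code exists.
        """
        rule = self.rule(name)
        for prefix in rule.include:
            for code in _completions(prefix):
                if self.classify_code(code) == frozenset({name}):
                    return code
        raise RuleTableError(f"no unambiguous representative ATC code for {name!r}")


def _completions(prefix: str, n_alt: int = 8) -> Iterable[str]:
    """Candidate full 7-character ATC codes extending ``prefix``.

    The ATC position pattern is letter, 2 digits, 2 letters, 2 digits
    (e.g. ``A02BC01``); missing positions are filled from small alternative
    sets so an exclude prefix blocking the first candidate is sidestepped.
    """
    if len(prefix) == 7:
        yield prefix
        return
    letters = "ABCDEFGH"[:n_alt]
    digits = [f"{i:02d}" for i in range(1, n_alt + 1)]
    for d2 in digits:
        for l2 in letters:
            for l1 in letters:
                for d1 in digits:
                    code = prefix
                    if len(code) == 1:
                        code += d1
                    if len(code) == 3:
                        code += l1
                    if len(code) == 4:
                        code += l2
                    if len(code) == 5:
                        code += d2
                    yield code
                    if len(prefix) >= 3:
                        break  # d1 unused
                if len(prefix) >= 4:
                    break  # l1 unused
            if len(prefix) >= 5:
                break  # l2 unused


def _read_csv(path: str | PathLike) -> list[dict[str, str]]:
    import csv

    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise RuleTableError(f"{path}: empty file")
        return [dict(row) for row in reader]


def load_conflict_map(path: str | PathLike) -> dict[str, frozenset[str]]:
    """Read an index-condition conflict CSV (index_condition, suppressed_comorbidity)."""
    rows = _read_csv(path)
    out: dict[str, set[str]] = {}
    for i, row in enumerate(rows, start=2):
        try:
            cond = row["index_condition"].strip()
            name = row["suppressed_comorbidity"].strip()
        except KeyError as exc:
            raise RuleTableError(f"{path} line {i}: missing column {exc}") from None
        out.setdefault(cond, set()).add(name)
    return {k: frozenset(v) for k, v in out.items()}


def load_rule_table(
    rules_path: str | PathLike,
    conflicts_path: str | PathLike | None = None,
) -> ComorbidityRuleTable:
    """Parse a comorbidity rule CSV (comorbidity, atc_prefix, action).

    Prefixes are normalised to upper case; ``action`` is ``include`` or
    ``exclude``.  Malformed rows raise :class:`RuleTableError` naming the row.
    """
    rows = _read_csv(rules_path)
    if not rows:
        raise RuleTableError(f"{rules_path}: no rule rows")
    include: dict[str, list[str]] = {}
    exclude: dict[str, list[str]] = {}
    order: list[str] = []
    for i, row in enumerate(rows, start=2):
        try:
            name = row["comorbidity"].strip()
            prefix = normalise_atc(row["atc_prefix"])
            action = row["action"].strip().lower()
        except (KeyError, AttributeError):
            raise RuleTableError(f"{rules_path} line {i}: malformed row {row!r}") from None
        if not is_valid_atc_prefix(prefix):
            raise RuleTableError(f"{rules_path} line {i}: malformed ATC prefix {prefix!r}")
        if action not in ("include", "exclude"):
            raise RuleTableError(f"{rules_path} line {i}: unknown action {action!r}")
        if name not in order:
            order.append(name)
        (include if action == "include" else exclude).setdefault(name, []).append(prefix)
    rules = [
        ComorbidityRule(
            name=n,
            include=tuple(include.get(n, ())),
            exclude=tuple(exclude.get(n, ())),
        )
        for n in order
    ]
    conflicts = load_conflict_map(conflicts_path) if conflicts_path is not None else {}
    return ComorbidityRuleTable(rules=rules, conflicts=conflicts)


@lru_cache(maxsize=1)
def default_rule_table() -> ComorbidityRuleTable:
    """The shipped 21-comorbidity table with its 22-condition conflict map."""
    data = resources.files("trialmorb.data")
    with resources.as_file(data / "comorbidity_rules.csv") as rp, resources.as_file(
        data / "index_conflicts.csv"
    ) as cp:
        table = load_rule_table(rp, cp)
    if len(table.rules) != 21:
        raise RuleTableError(
            f"default table must define 21 comorbidities, found {len(table.rules)}"
        )
    return table
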