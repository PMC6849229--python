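"""Internal-consistency checks against published summary estimates.

The original person-level data live in restricted safe havens, so the
published per-condition summary table (mean counts, their ratio, and the
proportion with count ≥ 2, each with a 95% UI) is the only public anchor.
Two families of checks verify that this package's operators reproduce the
arithmetic relationships inside that table:

* **Poisson tail checks** — for multi-trial indications the published trial
  proportion with count ≥ 2 was derived from the modelled mean count
  through the Poisson PMF, so applying :func:`pmf_profile` /
  :func:`prop_at_least` to the printed mean (and its UI bounds) must give
  back the printed proportion to 2 dp.  This plug-in identity holds for
  asthma, hypertension, migraine, psoriasis and psoriatic arthropathy; for
  type 2 diabetes and osteoporosis the printed proportion differs from the
  plug-in transform (those cells were evidently averaged over draws rather
  than transformed at the point estimate), so they are not in the check set.

* **Ratio checks** — the printed ratio of mean counts must equal the ratio
  of the printed means to 2 dp where the community UI is tight enough for
  the per-draw pairing not to move the second decimal (osteoarthritis, the
  single-trial indication with the most precise estimates).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .inference import pmf_profile, prop_at_least

__all__ = [
    "CheckResult",
    "published_summaries",
    "poisson_tail_check",
    "ratio_check",
    "CHECKS",
    "run_check",
    "run_all_checks",
    "POISSON_TAIL_CONDITIONS",
    "RATIO_CONDITIONS",
]

#: Conditions whose printed trial P(>= 2) equals the Poisson plug-in to 2 dp.
POISSON_TAIL_CONDITIONS = (
    "asthma",
    "hypertension",
    "migraine",
    "psoriasis",
    "psoriatic_arthropathy",
)

#: Conditions whose printed ratio equals the ratio of printed means to 2 dp.
RATIO_CONDITIONS = ("osteoarthritis",)


@dataclass(frozen=True)
class CheckResult:
    name: str
    computed: float
    expected: float
    passed: bool
    detail: str = ""

    def __str__(self) -> str:
        verdict = "PASS" if self.passed else "FAIL"
        return f"{self.name}: computed {self.computed:.2f} vs published {self.expected:.2f} [{verdict}] {self.detail}"


def published_summaries() -> pd.DataFrame:
    """Published per-condition summary estimates, indexed by condition."""
    with resources.as_file(
        resources.files("trialmorb.data") / "published_count_summaries.csv"
    ) as p:
        return pd.read_csv(p).set_index("condition")


def poisson_tail_check(condition: str, which: str = "point") -> CheckResult:
    """Does the Poisson plug-in of the printed trial mean give the printed P(>=2)?

    ``which`` selects the point estimate or a UI bound (``point`` / ``lo`` /
    ``hi``): the published interval for the proportion was obtained by
    transforming the mean's interval through the same monotone map.
    """
    pub = published_summaries()
    if condition not in pub.index:
        raise KeyError(f"no published summary for {condition!r}")
    col = {"point": "trial_mean", "lo": "trial_mean_lo", "hi": "trial_mean_hi"}[which]
    target_col = {
        "point": "trial_p_ge2",
        "lo": "trial_p_ge2_lo",
        "hi": "trial_p_ge2_hi",
    }[which]
    lam = float(pub.loc[condition, col])
    expected = float(pub.loc[condition, target_col])
    computed = prop_at_least(pmf_profile(lam), 2)
    return CheckResult(
        name=f"{condition}_prop_ge2_{which}" if which != "point" else f"{condition}_prop_ge2",
        computed=computed,
        expected=expected,
        passed=round(computed, 2) == round(expected, 2),
        detail=f"Poisson tail at mean count {lam}",
    )


def ratio_check(condition: str) -> CheckResult:
    """Does the ratio of printed mean counts round to the printed ratio?"""
    pub = published_summaries()
    if condition not in pub.index:
        raise KeyError(f"no published summary for {condition!r}")
    c = float(pub.loc[condition, "community_mean"])
    t = float(pub.loc[condition, "trial_mean"])
    expected = float(pub.loc[condition, "ratio"])
    computed = c / t
    return CheckResult(
        name=f"{condition}_ratio",
        computed=computed,
        expected=expected,
        passed=round(computed, 2) == round(expected, 2),
        detail=f"{c} / {t}",
    )


def _build_registry() -> dict:
    reg = {}
    for cond in POISSON_TAIL_CONDITIONS:
        reg[f"{cond}_prop_ge2"] = lambda c=cond: poisson_tail_check(c, "point")
        reg[f"{cond}_prop_ge2_lo"] = lambda c=cond: poisson_tail_check(c, "lo")
        reg[f"{cond}_prop_ge2_hi"] = lambda c=cond: poisson_tail_check(c, "hi")
    for cond in RATIO_CONDITIONS:
        reg[f"{cond}_ratio"] = lambda c=cond: ratio_check(c)
    return reg


#: Registry of named consistency checks.
CHECKS = _build_registry()


def run_check(name: str) -> CheckResult:
    """Run one registered consistency check by name."""
    if name not in CHECKS:
        raise KeyError(f"unknown check {name!r}; known: {sorted(CHECKS)}")
    return CHECKS[name]()


def run_all_checks() -> list[CheckResult]:
    return [CHECKS[name]() for name in sorted(CHECKS)]
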