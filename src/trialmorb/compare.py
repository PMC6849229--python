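"""Pre-specified community-vs-trial comparison statistics with 95% UIs.

Three statistics summarise how much more multimorbid community patients are
than trial participants with the same index condition:

1. the ratio of mean comorbidity counts (community : trials);
2. the ratio of the proportions with a count ≥ 2 (the usual
   "high multimorbidity" threshold: two comorbidities beside the index
   condition, i.e. three conditions overall);
3. the proportion of community patients with a count strictly greater than
   the trial median count.

Each is computed per paired simulation draw (1000 Dirichlet or posterior
draws on each side) and summarised by its mean and the 2.5th/97.5th
nearest-rank percentiles — so the uncertainty interval reflects both
populations' sampling uncertainty.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .aggregate import K_MAX
from .inference import DirichletDraws, PosteriorDraws, pmf_profile, prop_at_least

__all__ = [
    "Estimate",
    "ComparisonSummary",
    "mean_count",
    "ratio_of_means",
    "ratio_prop_at_least2",
    "discrete_median",
    "prop_above_trial_median",
    "percentile_interval",
    "compare_condition",
    "build_comparison_table",
]

MIN_SAMPLES = 40


@dataclass(frozen=True)
class Estimate:
    """Point estimate with a 95% uncertainty interval."""

    point: float
    lower: float
    upper: float

    def __post_init__(self):
        if not (self.lower <= self.point + 1e-12 and self.point <= self.upper + 1e-12):
            raise ValueError(f"interval does not bracket point: {self}")

    def round(self, nd: int = 2) -> "Estimate":
        return Estimate(round(self.point, nd), round(self.lower, nd), round(self.upper, nd))

    def __str__(self) -> str:
        return f"{self.point:.2f} ({self.lower:.2f}–{self.upper:.2f})"


@dataclass(frozen=True)
class ComparisonSummary:
    """Per-condition comparison row (Table-2 style)."""

    condition: str
    community_mean: Estimate
    trial_mean: Estimate
    ratio_means: Estimate
    community_p_ge2: Estimate
    trial_p_ge2: Estimate
    ratio_p_ge2: Estimate
    trial_median: int
    prop_above_median: Estimate
    n_trials: int = 0


def mean_count(draws) -> np.ndarray:
    """Per-draw mean comorbidity count.

    For Dirichlet proportion draws the mean is ``sum_k k p_k``; for Poisson
    random-effects posterior draws it is the population rate itself.
    """
    if isinstance(draws, DirichletDraws):
        if draws.n_draws == 0:
            raise ValueError("no draws")
        k = np.arange(draws.k_max + 1)
        return draws.draws @ k
    if isinstance(draws, PosteriorDraws):
        return np.asarray(draws.lambda_pop, float)
    arr = np.asarray(draws, float)
    if arr.size == 0:
        raise ValueError("no draws")
    return arr


def _summarise(per_draw: np.ndarray) -> Estimate:
    lo, hi = percentile_interval(per_draw)
    return Estimate(point=float(np.mean(per_draw)), lower=lo, upper=hi)


def ratio_of_means(community_means: np.ndarray, trial_means: np.ndarray) -> tuple[Estimate, np.ndarray]:
    """Community:trial ratio of mean counts, per paired draw.

    Draws are paired by index (equal lengths required); the point estimate
    is the mean of the per-draw ratios and the UI its 2.5/97.5 percentiles.
    Any non-positive trial mean draw is an error (the ratio is undefined).
    """
    c = np.asarray(community_means, float)
    t = np.asarray(trial_means, float)
    if c.shape != t.shape:
        raise ValueError("draw vectors must have equal length for pairing")
    if (t <= 0).any():
        raise ValueError("trial mean draws must be positive")
    ratios = c / t
    return _summarise(ratios), ratios


def ratio_prop_at_least2(community_draws, trial_draws) -> tuple[Estimate, np.ndarray]:
    """Ratio of the proportions with comorbidity count ≥ 2, per paired draw."""
    c = np.asarray(prop_at_least(community_draws, 2), float)
    t = np.asarray(prop_at_least(trial_draws, 2), float)
    if c.shape != t.shape:
        raise ValueError("draw vectors must have equal length for pairing")
    if (t <= 0).any():
        raise ValueError("trial P(count >= 2) draws must be positive")
    ratios = c / t
    return _summarise(ratios), ratios


def discrete_median(proportions) -> int:
    """Median of a discrete count distribution: smallest k with CDF ≥ 0.5."""
    p = np.asarray(proportions, float)
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("proportions must sum to 1")
    cdf = np.cumsum(p)
    return int(np.argmax(cdf >= 0.5 - 1e-12))


def prop_above_trial_median(community_draws, trial_median: int) -> tuple[Estimate, np.ndarray]:
    """Per-draw proportion of community patients strictly above the trial median."""
    if isinstance(community_draws, DirichletDraws):
        kmax = community_draws.k_max
        if trial_median >= kmax:
            per_draw = np.zeros(community_draws.n_draws)
        else:
            per_draw = community_draws.draws[:, trial_median + 1 :].sum(axis=1)
    else:
        per_draw = np.asarray(prop_at_least(community_draws, trial_median + 1), float)
    return _summarise(per_draw), per_draw


def percentile_interval(
    samples, lower_pct: float = 2.5, upper_pct: float = 97.5
) -> tuple[float, float]:
    """Nearest-rank percentile interval (no interpolation).

    The p-th rank percentile of n sorted samples is the value at rank
    ``ceil(p/100 * n)`` (1-based).  Requires at least 40 samples so the 2.5th
    percentile rank is meaningful.
    """
    x = np.sort(np.asarray(samples, float))
    n = len(x)
    if n < MIN_SAMPLES:
        raise ValueError(f"need >= {MIN_SAMPLES} samples for percentile interval, got {n}")

    def rank(p: float) -> int:
        return max(int(np.ceil(p / 100.0 * n)), 1)

    lo, hi = x[rank(lower_pct) - 1], x[rank(upper_pct) - 1]
    return float(lo), float(hi)


def _trial_point_proportions(trial_draws, k_max: int = K_MAX) -> np.ndarray:
    """Point count distribution for the trial side (for the median)."""
    if isinstance(trial_draws, DirichletDraws):
        p = trial_draws.draws.mean(axis=0)
        return p / p.sum()
    lam = float(np.mean(mean_count(trial_draws)))
    prof = pmf_profile(lam, k_max=k_max)
    p = np.append(prof.probs, prof.tail)
    return p / p.sum()


def compare_condition(
    condition: str,
    community_draws: DirichletDraws,
    trial_draws,
    n_trials: int = 0,
) -> ComparisonSummary:
    """All three pre-specified statistics for one index condition.

    ``community_draws`` are (standardised) Dirichlet proportion draws;
    ``trial_draws`` are Poisson-RE posterior draws (multi-trial indication)
    or Dirichlet draws (single trial).  The trial median is taken from the
    trial side's point count distribution.
    """
    comm_means = mean_count(community_draws)
    trial_means = mean_count(trial_draws)
    ratio, _ = ratio_of_means(comm_means, trial_means)
    ratio_p2, _ = ratio_prop_at_least2(community_draws, trial_draws)
    median = discrete_median(_trial_point_proportions(trial_draws))
    above, _ = prop_above_trial_median(community_draws, median)
    return ComparisonSummary(
        condition=condition,
        community_mean=_summarise(comm_means),
        trial_mean=_summarise(trial_means),
        ratio_means=ratio,
        community_p_ge2=_summarise(np.asarray(prop_at_least(community_draws, 2), float)),
        trial_p_ge2=_summarise(np.asarray(prop_at_least(trial_draws, 2), float)),
        ratio_p_ge2=ratio_p2,
        trial_median=median,
        prop_above_median=above,
        n_trials=n_trials,
    )


def build_comparison_table(summaries: list[ComparisonSummary]) -> pd.DataFrame:
    """Report table: one row per condition, descending community mean count.

    Formatted columns use 2-dp ``"x.xx (l–u)"`` strings; the raw point
    estimates are kept alongside for machine reading.
    """
    if not summaries:
        raise ValueError("no conditions to report")
    ordered = sorted(summaries, key=lambda s: s.community_mean.point, reverse=True)
    rows = []
    for s in ordered:
        rows.append(
            {
                "condition": s.condition,
                "community_mean": str(s.community_mean),
                "trial_mean": str(s.trial_mean),
                "ratio_means": str(s.ratio_means),
                "community_p_ge2": str(s.community_p_ge2),
                "trial_p_ge2": str(s.trial_p_ge2),
                "ratio_p_ge2": str(s.ratio_p_ge2),
                "trial_median": s.trial_median,
                "prop_above_median": str(s.prop_above_median),
                "n_trials": s.n_trials,
                "community_mean_point": s.community_mean.point,
                "trial_mean_point": s.trial_mean.point,
                "ratio_means_point": s.ratio_means.point,
            }
        )
    return pd.DataFrame(rows)
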