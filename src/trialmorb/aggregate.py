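"""Disclosure-safe aggregation and direct age–sex standardisation.

Safe havens export only aggregate data, so person-level comorbidity counts
are collapsed into per-(condition, age-band, sex) *count distributions* —
how many people have 0, 1, 2, … comorbidities — before anything leaves the
secure environment.  Counts above ``K_max`` (default 12) are pooled into the
top cell, and small cells can be merged until no non-zero cell is below a
disclosure threshold.

Community distributions are then *directly standardised* to the trials'
age–sex structure: stratum weights are the pooled trial age–sex composition
for the condition, and the standardised proportion at count ``k`` is the
weighted average of the stratum-specific proportions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "K_MAX",
    "DEFAULT_DISCLOSURE_THRESHOLD",
    "AgeBands",
    "CountDistribution",
    "aggregate_counts",
    "disclosure_control",
    "trial_age_sex_weights",
    "standardise_community",
    "distributions_to_frame",
]

#: Top comorbidity-count cell; higher counts are pooled here.
K_MAX = 12

DEFAULT_DISCLOSURE_THRESHOLD = 5

SEXES = ("female", "male")


@dataclass(frozen=True)
class AgeBands:
    """Closed-open age bands partitioning the supported age range."""

    edges: tuple[tuple[int, int], ...] = (
        (18, 40), (40, 50), (50, 60), (60, 70), (70, 80), (80, 105),
    )

    def __post_init__(self):
        for (lo, hi), (lo2, _) in zip(self.edges, self.edges[1:]):
            if hi != lo2:
                raise ValueError("age bands must be contiguous")
        if any(lo >= hi for lo, hi in self.edges):
            raise ValueError("age bands must be non-empty intervals")

    @property
    def labels(self) -> list[str]:
        out = []
        for i, (lo, hi) in enumerate(self.edges):
            out.append(f"{lo}+" if i == len(self.edges) - 1 else f"{lo}-{hi - 1}")
        return out

    def label_of(self, age: float) -> str:
        for (lo, hi), lab in zip(self.edges, self.labels):
            if lo <= age < hi:
                return lab
        raise ValueError(f"age {age} outside all bands")

    def assign(self, ages: pd.Series) -> pd.Series:
        """Vectorised band label per age; NaN for out-of-range ages."""
        edges = [lo for lo, _ in self.edges] + [self.edges[-1][1]]
        return pd.cut(ages, bins=edges, right=False, labels=self.labels)

    @property
    def strata(self) -> list[tuple[str, str]]:
        return [(band, sex) for band in self.labels for sex in SEXES]


@dataclass(frozen=True)
class CountDistribution:
    """People at each comorbidity count 0..K_max in one (condition, stratum) cell."""

    condition: str
    n_at_count: tuple[int, ...]
    stratum: Optional[tuple[str, str]] = None  # (age_band, sex)

    def __post_init__(self):
        if any(n < 0 for n in self.n_at_count):
            raise ValueError("negative cell count")

    @property
    def total(self) -> int:
        return int(sum(self.n_at_count))

    @property
    def k_max(self) -> int:
        return len(self.n_at_count) - 1

    @property
    def proportions(self) -> np.ndarray:
        if self.total == 0:
            raise ValueError("empty distribution has no proportions")
        return np.asarray(self.n_at_count, dtype=float) / self.total

    def mean(self) -> float:
        return float(np.dot(np.arange(len(self.n_at_count)), self.proportions))


def aggregate_counts(
    profiles: pd.DataFrame,
    bands: AgeBands | None = None,
    k_max: int = K_MAX,
) -> list[CountDistribution]:
    """Stratified count distributions from person-level comorbidity profiles.

    ``profiles`` needs ``index_condition``, ``age``, ``sex`` and ``count``
    columns (as produced by ``classify_cohort``).  One distribution is
    returned per observed (condition, age-band, sex) cell; counts above
    ``k_max`` are pooled into the top cell and totals conserve the number of
    people.  People with ages outside every band raise an error listing ids.
    """
    if profiles.empty:
        return []
    if bands is None:
        bands = AgeBands()
    band_labels = bands.assign(profiles["age"])
    if band_labels.isna().any():
        bad = profiles.loc[band_labels.isna(), "person_id"].tolist()
        raise ValueError(f"ages outside all bands for: {bad}")
    counts = np.minimum(profiles["count"].to_numpy(int), k_max)
    work = pd.DataFrame(
        {
            "condition": profiles["index_condition"].to_numpy(),
            "band": band_labels.astype(str).to_numpy(),
            "sex": profiles["sex"].to_numpy(),
            "count": counts,
        }
    )
    out = []
    for (cond, band, sex), grp in work.groupby(
        ["condition", "band", "sex"], sort=True
    ):
        vec = np.bincount(grp["count"], minlength=k_max + 1)
        out.append(
            CountDistribution(
                condition=str(cond),
                stratum=(str(band), str(sex)),
                n_at_count=tuple(int(v) for v in vec),
            )
        )
    return out


def disclosure_control(
    dist: CountDistribution, threshold: int = DEFAULT_DISCLOSURE_THRESHOLD
) -> tuple[CountDistribution, list[tuple[int, int]]]:
    """Merge small cells until none is below the disclosure threshold.

    Scanning from the top count down, any non-zero cell below ``threshold``
    is merged into the adjacent lower cell; if the violating cell is count 0
    (no lower neighbour) the nearest non-zero cell above is pulled down into
    it.  Stops when all non-zero cells meet the threshold or a single cell
    remains.  Returns the controlled distribution and the list of merges as
    ``(from_count, to_count)`` pairs.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    n = list(dist.n_at_count)
    merges: list[tuple[int, int]] = []
    while True:
        nonzero = [k for k, v in enumerate(n) if v > 0]
        violators = [k for k in nonzero if n[k] < threshold]
        if not violators or len(nonzero) <= 1:
            break
        k = max(violators)
        if k > 0:
            n[k - 1] += n[k]
            n[k] = 0
            merges.append((k, k - 1))
        else:
            j = min(j for j in nonzero if j > 0)
            n[0] += n[j]
            n[j] = 0
            merges.append((j, 0))
    return replace(dist, n_at_count=tuple(n)), merges


def trial_age_sex_weights(
    participants: pd.DataFrame, bands: AgeBands | None = None
) -> pd.Series:
    """Pooled trial age–sex composition as standardisation weights.

    Weight of a stratum = participants in that stratum across all the
    condition's trials / total participants; weights sum to 1.  Expects a
    participants table (one condition) with ``age`` and ``sex`` columns.
    """
    if participants.empty:
        raise ValueError("no trial participants to weight")
    if bands is None:
        bands = AgeBands()
    band_labels = bands.assign(participants["age"])
    if band_labels.isna().any():
        bad = participants.loc[band_labels.isna(), "person_id"].tolist()
        raise ValueError(f"ages outside all bands for: {bad}")
    tab = (
        pd.DataFrame({"band": band_labels.astype(str), "sex": participants["sex"]})
        .value_counts(["band", "sex"])
        .sort_index()
    )
    return tab / tab.sum()


def standardise_community(
    stratum_dists: Sequence[CountDistribution] | Mapping[tuple[str, str], CountDistribution],
    weights: pd.Series,
) -> np.ndarray:
    """Directly standardise community count distributions to trial weights.

    Returns the standardised proportion vector
    ``p_k = sum_s w_s * n_{s,k} / N_s`` over counts 0..K_max; proportions
    sum to 1 (up to rounding).  Every weighted stratum must be present in
    the community data with a positive total.
    """
    if isinstance(stratum_dists, Mapping):
        by_stratum = dict(stratum_dists)
    else:
        by_stratum = {d.stratum: d for d in stratum_dists}
    if abs(float(weights.sum()) - 1.0) > 1e-9:
        raise ValueError("weights must sum to 1")
    k_sizes = {len(d.n_at_count) for d in by_stratum.values()}
    if len(k_sizes) != 1:
        raise ValueError("stratum distributions have inconsistent K_max")
    out = np.zeros(k_sizes.pop())
    for stratum, w in weights.items():
        key = tuple(stratum)
        if key not in by_stratum:
            raise ValueError(f"stratum {key} missing from community data")
        d = by_stratum[key]
        if d.total == 0:
            raise ValueError(f"stratum {key} has no community patients")
        out += float(w) * d.proportions
    return out


def distributions_to_frame(dists: Sequence[CountDistribution]) -> pd.DataFrame:
    """Tidy export: condition, age_band, sex, count, n (one row per cell)."""
    rows = []
    for d in dists:
        band, sex = d.stratum if d.stratum else ("", "")
        for k, n in enumerate(d.n_at_count):
            rows.append((d.condition, band, sex, k, n))
    return pd.DataFrame(rows, columns=["condition", "age_band", "sex", "count", "n"])
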