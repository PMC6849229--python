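"""End-to-end pipeline: simulate → code → aggregate → standardise → infer → compare.

``run_simulate`` materialises a synthetic study (trial and community tables
plus ground truth) to a dataset directory; ``run_analysis`` reads such a
directory, applies the full medication-based comorbidity pipeline on both
sides, and writes disclosure-safe aggregates, 1000 uncertainty draws per
condition and the comparison report.  Every filter logs its drop counts and
a manifest records the seed and a configuration hash, so an identical
config + seed reproduces the outputs byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .aggregate import (
    DEFAULT_DISCLOSURE_THRESHOLD,
    K_MAX,
    AgeBands,
    aggregate_counts,
    disclosure_control,
    distributions_to_frame,
    standardise_community,
    trial_age_sex_weights,
)
from .coding import (
    assign_atc,
    classify_cohort,
    community_window_filter,
    trial_window_filter,
)
from .compare import ComparisonSummary, build_comparison_table, compare_condition
from .inference import (
    N_DRAWS,
    dirichlet_draws,
    fit_poisson_re,
    standardised_dirichlet_draws,
)
from .rules import ComorbidityRuleTable, default_rule_table, load_rule_table
from .simulate import SimulationConfig, simulate_community, simulate_trials

__all__ = ["run_simulate", "run_analysis", "AnalysisConfig"]

logger = logging.getLogger(__name__)


def _config_hash(config: SimulationConfig) -> str:
    return hashlib.sha256(config.model_dump_json().encode()).hexdigest()[:16]


def run_simulate(
    config: SimulationConfig,
    out_dir: str | Path,
    rules: ComorbidityRuleTable | None = None,
) -> Path:
    """Generate and write the synthetic dataset directory.

    Writes ``participants.csv``, ``trial_medications.csv``,
    ``community.csv``, ``community_medications.csv``, the two ground-truth
    tables and ``manifest.json`` (seed, config, config hash, version).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if rules is None:
        rules = default_rule_table()
    participants, trial_meds, trial_truth = simulate_trials(config, rules)
    community, comm_meds, comm_truth = simulate_community(config, rules)
    participants.to_csv(out / "participants.csv", index=False)
    trial_meds.to_csv(out / "trial_medications.csv", index=False)
    community.to_csv(out / "community.csv", index=False)
    comm_meds.to_csv(out / "community_medications.csv", index=False)
    trial_truth.to_frame().to_csv(out / "trial_truth.csv", index=False)
    comm_truth.to_frame().to_csv(out / "community_truth.csv", index=False)
    manifest = {
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "config": json.loads(config.model_dump_json()),
        "version": __version__,
        "files": sorted(p.name for p in out.glob("*.csv")),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    logger.info("simulated dataset written to %s (hash %s)", out, manifest["config_hash"])
    return out


@dataclass(frozen=True)
class AnalysisConfig:
    """Knobs for the analysis half of the pipeline."""

    n_draws: int = N_DRAWS
    k_max: int = K_MAX
    disclosure_threshold: int = DEFAULT_DISCLOSURE_THRESHOLD
    prior_alpha: float = 1.0
    prior_mu_sd: float = 10.0
    prior_tau_sd: float = 1.0
    seed: int = 0
    mcmc_burn: int = 1200
    mcmc_steps: int = 500

    def __post_init__(self):
        if self.n_draws < 40:
            raise ValueError("need at least 40 draws for percentile intervals")


def run_analysis(
    data_dir: str | Path,
    out_dir: str | Path,
    config: AnalysisConfig | None = None,
    rules: ComorbidityRuleTable | None = None,
    rule_table_path: str | Path | None = None,
) -> pd.DataFrame:
    """Run the full comparison on a dataset directory; returns the report table.

    Trial side: medications are ATC-coded, restricted to drugs started on or
    before randomisation, classified, and summed per trial; indications with
    ≥ 2 trials get the Poisson random-effects posterior, single-trial
    indications Dirichlet resampling of the raw count distribution.
    Community side: 2011 prescriptions are classified, aggregated into
    age–sex count distributions (disclosure-controlled), and Dirichlet
    uncertainty is standardised to the pooled trial age–sex weights.
    """
    cfg = config or AnalysisConfig()
    data = Path(data_dir)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if rules is None:
        rules = (
            load_rule_table(rule_table_path) if rule_table_path else default_rule_table()
        )
    bands = AgeBands()

    participants = pd.read_csv(data / "participants.csv")
    trial_meds = pd.read_csv(data / "trial_medications.csv")
    community = pd.read_csv(data / "community.csv")
    comm_meds = pd.read_csv(data / "community_medications.csv")

    # --- trial side -------------------------------------------------------
    trial_meds = assign_atc(trial_meds)
    trial_meds = trial_window_filter(trial_meds, participants)
    trial_profiles = classify_cohort(trial_meds, participants, rules)
    trial_profiles.to_csv(out / "trial_profiles.csv", index=False)

    # --- community side ---------------------------------------------------
    comm_meds = assign_atc(comm_meds)
    comm_meds = community_window_filter(comm_meds)
    comm_profiles = classify_cohort(comm_meds, community, rules)
    comm_profiles.to_csv(out / "community_profiles.csv", index=False)

    comm_dists = aggregate_counts(comm_profiles, bands, cfg.k_max)
    controlled = []
    merge_log = []
    for d in comm_dists:
        dc, merges = disclosure_control(d, cfg.disclosure_threshold)
        controlled.append(dc)
        for frm, to in merges:
            merge_log.append((d.condition, *d.stratum, frm, to))
    distributions_to_frame(controlled).to_csv(out / "community_aggregates.csv", index=False)
    if merge_log:
        pd.DataFrame(
            merge_log, columns=["condition", "age_band", "sex", "from_count", "to_count"]
        ).to_csv(out / "disclosure_merges.csv", index=False)
    logger.info("disclosure control merged %d cells", len(merge_log))

    ss = np.random.SeedSequence([cfg.seed, 3])
    summaries: list[ComparisonSummary] = []
    conditions = sorted(participants["index_condition"].unique())
    diag_rows = {}
    for cond, child in zip(conditions, ss.spawn(len(conditions))):
        child_seeds = child.generate_state(2) % (2**31)
        part_c = participants[participants["index_condition"] == cond]
        tprof_c = trial_profiles[trial_profiles["index_condition"] == cond]

        # community draws standardised to this condition's trial age-sex mix
        weights = trial_age_sex_weights(part_c, bands)
        strata = {
            d.stratum: d
            for d in controlled
            if d.condition == cond
        }
        missing = [tuple(s) for s in weights.index if tuple(s) not in strata]
        if missing:
            raise ValueError(
                f"{cond}: community data missing weighted strata {missing}"
            )
        weights.rename("weight").reset_index().assign(condition=cond).to_csv(
            out / f"trial_weights_{cond}.csv", index=False
        )
        comm_draws = standardised_dirichlet_draws(
            strata,
            weights,
            n_draws=cfg.n_draws,
            prior_alpha=cfg.prior_alpha,
            seed=int(child_seeds[0]),
        )
        # standardised point distribution is exported alongside the draws
        std = standardise_community(strata, weights)
        pd.DataFrame(
            {"count": np.arange(len(std)), "proportion": std}
        ).to_csv(out / f"standardised_{cond}.csv", index=False)

        # trial draws: RE posterior across trials, or Dirichlet for one trial
        trial_stats = tprof_c.groupby("trial_id")["count"].agg(["sum", "size"])
        if len(trial_stats) >= 2:
            post = fit_poisson_re(
                trial_stats["sum"].to_numpy(),
                trial_stats["size"].to_numpy(),
                n_draws=cfg.n_draws,
                seed=int(child_seeds[1]),
                prior_mu_sd=cfg.prior_mu_sd,
                prior_tau_sd=cfg.prior_tau_sd,
                n_burn=cfg.mcmc_burn,
                n_steps=cfg.mcmc_steps,
            )
            trial_draws = post
            diag_rows[cond] = post.diagnostics
            np.savetxt(out / f"trial_lambda_draws_{cond}.csv",
                       post.lambda_pop, header="lambda_pop", comments="")
        else:
            counts = np.minimum(tprof_c["count"].to_numpy(int), cfg.k_max)
            vec = np.bincount(counts, minlength=cfg.k_max + 1)
            trial_draws = dirichlet_draws(
                vec, n_draws=cfg.n_draws, prior_alpha=cfg.prior_alpha,
                seed=int(child_seeds[1]),
            )
        summaries.append(
            compare_condition(cond, comm_draws, trial_draws, n_trials=len(trial_stats))
        )

    report = build_comparison_table(summaries)
    report.to_csv(out / "report.csv", index=False)
    (out / "report.json").write_text(
        json.dumps(report.to_dict(orient="records"), indent=2)
    )
    if diag_rows:
        (out / "mcmc_diagnostics.json").write_text(json.dumps(diag_rows, indent=2))
    logger.info("report written for %d conditions", len(summaries))
    return report
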