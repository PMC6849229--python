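"""Uncertainty quantification for aggregate comorbidity-count data.

Two simulation routes produce 1000 draws each, matching how uncertainty is
propagated when only aggregates leave the safe havens:

* **Dirichlet resampling** — for a single observed count distribution
  (one trial, or one community stratum) the vector of proportions is drawn
  from ``Dirichlet(n_k + alpha)``, the conjugate posterior of a multinomial
  with a symmetric prior.  Community uncertainty is propagated per age–sex
  stratum and the draws are weight-averaged
  (:func:`standardised_dirichlet_draws`).

* **Poisson random-effects meta-analysis** — for an indication with several
  trials, trial total counts are modelled as
  ``y_i ~ Poisson(n_i * lambda_i)`` with ``log lambda_i ~ Normal(mu, tau^2)``
  and weakly informative priors (``mu ~ Normal(0, 10)``,
  ``tau ~ HalfNormal(1)``).  The posterior is explored with an
  affine-invariant ensemble sampler (emcee); the population mean count is
  reported as ``exp(mu)`` per draw, with a predictive-trial alternative
  ``exp(mu + tau z)`` behind a flag.

Posterior mean-count draws are mapped to full count distributions through
the Poisson probability mass function over counts 0..12
(:func:`pmf_profile`); mass above 12 is kept as an explicit tail, never
renormalised away.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .aggregate import K_MAX, CountDistribution

__all__ = [
    "DirichletDraws",
    "PosteriorDraws",
    "PmfProfile",
    "dirichlet_draws",
    "standardised_dirichlet_draws",
    "fit_poisson_re",
    "pmf_profile",
    "prop_at_least",
]

N_DRAWS = 1000


@dataclass(frozen=True)
class DirichletDraws:
    """Resampled proportion vectors (n_draws × K_max+1) for one distribution."""

    draws: np.ndarray
    seed: int
    source: str = ""

    def __post_init__(self):
        d = np.asarray(self.draws)
        if d.ndim != 2:
            raise ValueError("draws must be a 2-D matrix")
        if (d < 0).any() or np.abs(d.sum(axis=1) - 1).max() > 1e-9:
            raise ValueError("each draw must be a probability vector")

    @property
    def n_draws(self) -> int:
        return self.draws.shape[0]

    @property
    def k_max(self) -> int:
        return self.draws.shape[1] - 1


@dataclass(frozen=True)
class PosteriorDraws:
    """Retained MCMC draws from the Poisson random-effects model."""

    lambda_pop: np.ndarray  # population mean count per draw, exp(mu)
    lambda_trials: np.ndarray  # n_draws × n_trials per-trial rates
    tau: np.ndarray  # heterogeneity SD per draw (log scale)
    diagnostics: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if (np.asarray(self.lambda_pop) <= 0).any() or (np.asarray(self.tau) < 0).any():
            raise ValueError("invalid posterior draws")

    @property
    def n_draws(self) -> int:
        return len(self.lambda_pop)


@dataclass(frozen=True)
class PmfProfile:
    """Poisson count probabilities over 0..K_max plus explicit tail mass."""

    probs: np.ndarray
    tail: float

    def __post_init__(self):
        p = np.asarray(self.probs)
        if (p < 0).any() or self.tail < -1e-12:
            raise ValueError("negative probability")
        if abs(p.sum() + self.tail - 1.0) > 1e-9:
            raise ValueError("profile does not sum to 1")


def dirichlet_draws(
    dist: CountDistribution | Sequence[int],
    n_draws: int = N_DRAWS,
    prior_alpha: float = 1.0,
    seed: int = 0,
) -> DirichletDraws:
    """Sample proportion vectors from ``Dirichlet(n_k + prior_alpha)``.

    ``prior_alpha`` must be positive whenever any cell is empty (an all-zero
    concentration is undefined); the default symmetric alpha of 1 gives every
    count value support.
    """
    if isinstance(dist, CountDistribution):
        counts = np.asarray(dist.n_at_count, dtype=float)
        source = f"{dist.condition}:{dist.stratum}"
    else:
        counts = np.asarray(dist, dtype=float)
        source = ""
    if counts.sum() <= 0 and prior_alpha <= 0:
        raise ValueError("all-zero concentration: empty distribution with alpha=0")
    if prior_alpha < 0:
        raise ValueError("prior_alpha must be non-negative")
    conc = counts + prior_alpha
    if (conc <= 0).any():
        raise ValueError("zero cells need prior_alpha > 0")
    rng = np.random.default_rng(seed)
    draws = rng.dirichlet(conc, size=n_draws)
    return DirichletDraws(draws=draws, seed=seed, source=source)


def standardised_dirichlet_draws(
    stratum_dists: Sequence[CountDistribution] | Mapping[tuple[str, str], CountDistribution],
    weights: pd.Series,
    n_draws: int = N_DRAWS,
    prior_alpha: float = 1.0,
    seed: int = 0,
) -> DirichletDraws:
    """Community uncertainty: per-stratum Dirichlet draws, weight-averaged.

    Each draw samples every stratum's proportion vector independently from
    its Dirichlet posterior and combines them with the trial age–sex weights,
    so the standardised distribution's sampling uncertainty reflects each
    stratum's own sample size.
    """
    if isinstance(stratum_dists, Mapping):
        by_stratum = dict(stratum_dists)
    else:
        by_stratum = {d.stratum: d for d in stratum_dists}
    if abs(float(weights.sum()) - 1.0) > 1e-9:
        raise ValueError("weights must sum to 1")
    rng = np.random.default_rng(seed)
    out = None
    for stratum, w in weights.items():
        key = tuple(stratum)
        if key not in by_stratum:
            raise ValueError(f"stratum {key} missing from community data")
        d = by_stratum[key]
        conc = np.asarray(d.n_at_count, dtype=float) + prior_alpha
        if (conc <= 0).any():
            raise ValueError("zero cells need prior_alpha > 0")
        draws = rng.dirichlet(conc, size=n_draws)
        out = float(w) * draws if out is None else out + float(w) * draws
    if out is None:
        raise ValueError("no strata to standardise")
    # guard rounding so rows sum to exactly 1
    out = out / out.sum(axis=1, keepdims=True)
    return DirichletDraws(draws=out, seed=seed, source="standardised-community")


def _log_posterior(theta: np.ndarray, y: np.ndarray, n: np.ndarray,
                   prior_mu_sd: float, prior_tau_sd: float) -> np.ndarray:
    """Vectorised log posterior over walker rows (mu, log_tau, log_lambda_i)."""
    theta = np.atleast_2d(theta)
    mu = theta[:, 0]
    log_tau = theta[:, 1]
    log_lam = theta[:, 2:]
    lp = np.full(theta.shape[0], -np.inf)
    ok = (
        (np.abs(mu) < 20)
        & (log_tau > -12)
        & (log_tau < 5)
        & (np.abs(log_lam) < 20).all(axis=1)
    )
    if not ok.any():
        return lp
    mu_, lt_, ll_ = mu[ok], log_tau[ok], log_lam[ok]
    tau = np.exp(lt_)
    val = -0.5 * (mu_ / prior_mu_sd) ** 2
    # half-normal prior on tau, with the log-scale Jacobian
    val += -0.5 * (tau / prior_tau_sd) ** 2 + lt_
    # random effects
    val += (
        -0.5 * ((ll_ - mu_[:, None]) / tau[:, None]) ** 2
        - np.log(tau)[:, None]
    ).sum(axis=1)
    # Poisson likelihood for trial totals with exposure offset n_i
    val += (y * ll_ - n * np.exp(ll_)).sum(axis=1)
    lp[ok] = val
    return lp


def fit_poisson_re(
    trial_totals: Sequence[float],
    trial_n: Sequence[int],
    *,
    n_draws: int = N_DRAWS,
    seed: int = 0,
    prior_mu_sd: float = 10.0,
    prior_tau_sd: float = 1.0,
    n_walkers: int | None = None,
    n_burn: int = 1200,
    n_steps: int = 500,
    predictive: bool = False,
    ess_floor: float = 100.0,
) -> PosteriorDraws:
    """Bayesian Poisson random-effects meta-analysis of trial mean counts.

    ``trial_totals[i]`` is the summed comorbidity count over the ``i``-th
    trial's ``trial_n[i]`` participants — the aggregate a safe haven can
    export; the model is equivalent to person-level Poisson sampling.
    Needs at least two trials (a single trial should use
    :func:`dirichlet_draws` instead).  Returns ``n_draws`` retained draws;
    ``lambda_pop`` is ``exp(mu)`` per draw, or the predictive-trial mean
    ``exp(mu + tau z)`` when ``predictive`` is set.  A minimum-ESS warning is
    raised (never silenced) when mixing is poor.
    """
    import emcee

    y = np.asarray(trial_totals, dtype=float)
    n = np.asarray(trial_n, dtype=float)
    if y.ndim != 1 or y.shape != n.shape:
        raise ValueError("trial_totals and trial_n must be equal-length vectors")
    if len(y) < 2:
        raise ValueError(
            "random-effects model needs >= 2 trials; use dirichlet_draws for a single trial"
        )
    if (n < 1).any() or (y < 0).any():
        raise ValueError("each trial needs n >= 1 and a non-negative total")

    ndim = 2 + len(y)
    nw = n_walkers or max(2 * ndim + 8, 48)
    rng = np.random.default_rng(seed)
    lam_hat = (y + 0.5) / n
    mu0 = float(np.mean(np.log(lam_hat)))
    tau0 = float(max(np.std(np.log(lam_hat)), 0.05))
    centre = np.concatenate([[mu0, np.log(tau0)], np.log(lam_hat)])
    p0 = centre + 0.05 * rng.standard_normal((nw, ndim))

    # differential-evolution moves mix far better than the default stretch
    # move once per-trial rates push the dimension past ~10
    moves = [(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)]
    sampler = emcee.EnsembleSampler(
        nw,
        ndim,
        _log_posterior,
        args=(y, n, prior_mu_sd, prior_tau_sd),
        vectorize=True,
        moves=moves,
    )
    sampler.random_state = np.random.RandomState(seed % 2**32).get_state()
    state = sampler.run_mcmc(p0, n_burn, progress=False)
    sampler.reset()
    sampler.run_mcmc(state, n_steps, progress=False)
    chain = sampler.get_chain()  # (n_steps, nw, ndim)

    flat = chain.reshape(-1, ndim)
    idx = np.linspace(0, len(flat) - 1, n_draws).astype(int)
    draws = flat[idx]
    mu_d, tau_d, ll_d = draws[:, 0], np.exp(draws[:, 1]), draws[:, 2:]
    if predictive:
        lambda_pop = np.exp(mu_d + tau_d * rng.standard_normal(n_draws))
    else:
        lambda_pop = np.exp(mu_d)

    diagnostics = _diagnostics(chain, sampler.acceptance_fraction)
    if diagnostics["min_ess"] < ess_floor:
        warnings.warn(
            f"Poisson RE sampler mixing is poor (min ESS "
            f"{diagnostics['min_ess']:.0f} < {ess_floor:.0f}); "
            "increase n_burn/n_steps",
            RuntimeWarning,
            stacklevel=2,
        )
    return PosteriorDraws(
        lambda_pop=lambda_pop,
        lambda_trials=np.exp(ll_d),
        tau=tau_d,
        diagnostics=diagnostics,
        seed=seed,
    )


def _diagnostics(chain: np.ndarray, acceptance: np.ndarray) -> dict:
    """Bulk ESS (mu and log tau) and mean acceptance fraction."""
    import arviz as az

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        # arviz expects (chains, draws)
        ess_mu = float(az.ess(np.ascontiguousarray(chain[:, :, 0].T)))
        ess_tau = float(az.ess(np.ascontiguousarray(chain[:, :, 1].T)))
    return {
        "ess_mu": ess_mu,
        "ess_log_tau": ess_tau,
        "min_ess": min(ess_mu, ess_tau),
        "mean_acceptance": float(np.mean(acceptance)),
    }


def pmf_profile(lam: float, k_max: int = K_MAX) -> PmfProfile:
    """Poisson count probabilities ``e^-lam lam^k / k!`` for k = 0..k_max.

    The mass above ``k_max`` is reported as an explicit tail; nothing is
    renormalised.
    """
    if not lam > 0:
        raise ValueError("lambda must be positive")
    k = np.arange(k_max + 1)
    probs = stats.poisson.pmf(k, lam)
    tail = float(stats.poisson.sf(k_max, lam))
    return PmfProfile(probs=probs, tail=tail)


def prop_at_least(draws, k: int):
    """Probability of a comorbidity count ≥ k (tail-inclusive).

    Accepts a :class:`PmfProfile` (returns a scalar), a
    :class:`DirichletDraws` (returns one value per draw; ``k = K_max + 1``
    gives 0 by convention, beyond errors), a :class:`PosteriorDraws` or a
    plain array of Poisson means (per-draw Poisson survival probabilities).
    """
    if k < 0:
        raise ValueError("k must be non-negative")
    if isinstance(draws, PmfProfile):
        if k == 0:
            return 1.0
        if k > len(draws.probs):  # beyond K_max + 1 the profile cannot resolve
            raise ValueError(f"k={k} beyond the profile's resolved range")
        return float(np.sum(draws.probs[k:]) + draws.tail)
    if isinstance(draws, DirichletDraws):
        kmax = draws.k_max
        if k > kmax + 1:
            raise ValueError(f"k={k} beyond K_max+1={kmax + 1} for Dirichlet draws")
        if k == kmax + 1:
            return np.zeros(draws.n_draws)
        return draws.draws[:, k:].sum(axis=1)
    lam = draws.lambda_pop if isinstance(draws, PosteriorDraws) else np.asarray(draws, float)
    if (np.asarray(lam) <= 0).any():
        raise ValueError("Poisson means must be positive")
    return stats.poisson.sf(k - 1, lam)
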