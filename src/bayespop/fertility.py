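"""Gompertz model for the total fertility rate and its Bayesian fit.

The TFR of a country in demographic transition declines along an S-shaped
path from a high pre-transition plateau towards a low post-transition level.
We model the observed annual TFR series as

    Y_i = h(t_i) + e_i,        e_i ~ iid N(0, 1/tau)

with the Gompertz mean curve

    h(t) = d + c * exp(-exp(-b * (t - a)))

where ``t`` is a 1-based year index (first observation year -> t = 1),
``d`` is the early-time level, ``d + c`` the late-time asymptote (``c`` is
negative for a fertility decline), ``b > 0`` the transition rate per year
and ``a`` the index at which the decline is steepest.

The posterior over (a, b, c, d, tau) is sampled by Metropolis-within-Gibbs:
random-walk updates for the curve parameters and an exact gamma draw for the
precision, whose conditional is conjugate given the mean curve.

Priors default to independent N(0, 3^2) on the curve parameters and
gamma(0.001, 0.001) on tau.  The normal scale is deliberately weakly
informative rather than arbitrarily diffuse: under near-flat priors the
likelihood has an unbounded ridge (b -> 0 with |c|, |d| growing without
limit reproduces an almost-linear decline equally well), so the posterior
mean of the curve parameters is then dominated by the prior's tails rather
than the data.  A scale of 3 is diffuse relative to the magnitude of TFR
(single digits) while excluding that degenerate regime.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .mcmc import (
    ChainSet,
    GammaPrior,
    MCMCConfig,
    NormalPrior,
    RegressionPriors,
    gelman_rubin,
    run_sampler,
)

__all__ = [
    "TFRSeries",
    "GompertzParams",
    "ASFRSchedule",
    "REPRODUCTIVE_AGE_GROUPS",
    "default_fertility_priors",
    "gompertz_mean",
    "fertility_log_posterior",
    "fit_fertility",
    "project_tfr",
    "tfr_to_asfr",
    "ProjectedTrajectories",
]

REPRODUCTIVE_AGE_GROUPS: tuple[str, ...] = (
    "15-19",
    "20-24",
    "25-29",
    "30-34",
    "35-39",
    "40-44",
    "45-49",
)

_PARAM_NAMES = ("a", "b", "c", "d", "tau")


@dataclass(frozen=True)
class TFRSeries:
    """An observed annual total-fertility-rate series.

    ``years`` must be consecutive calendar years; the model time index is
    1-based, ``t_i = i`` for the i-th observation.
    """

    years: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        years = np.asarray(self.years, dtype=int)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "values", values)
        if years.size != values.size:
            raise ValueError("years and values must have equal length")
        if years.size and not np.all(np.diff(years) == 1):
            raise ValueError("years must be strictly increasing and consecutive")
        if np.any(values <= 0) or np.any(values >= 10):
            raise ValueError("TFR values must lie in (0, 10)")

    def __len__(self) -> int:
        return self.years.size

    @property
    def t_index(self) -> np.ndarray:
        """1-based model time index (first year -> 1)."""
        return np.arange(1, len(self) + 1)

    @property
    def first_year(self) -> int:
        return int(self.years[0])

    def year_to_index(self, year) -> np.ndarray:
        """Map calendar years (possibly fractional) onto the model index."""
        return np.asarray(year, dtype=float) - self.first_year + 1.0


@dataclass(frozen=True)
class GompertzParams:
    """Parameters of the Gompertz TFR regression.

    ``a`` locates the steepest decline (index units), ``b`` is the
    transition rate per year, ``c`` the (negative, for decline) span between
    the early and late asymptotes, ``d`` the early-time level and ``tau``
    the error precision (1/TFR^2).
    """

    a: float
    b: float
    c: float
    d: float
    tau: float

    def __post_init__(self) -> None:
        vals = (self.a, self.b, self.c, self.d, self.tau)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("Gompertz parameters must be finite")
        if self.tau <= 0:
            raise ValueError("precision tau must be positive")

    @property
    def sigma(self) -> float:
        """Residual SD, tau**-0.5."""
        return self.tau ** -0.5

    def as_array(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c, self.d, self.tau])


@dataclass(frozen=True)
class ASFRSchedule:
    """Age-specific fertility rates over the seven reproductive age groups.

    ``rates`` are births per woman per year; five times their sum recovers
    the TFR the schedule was built from.  ``weights`` is the non-negative
    proportional pattern (summing to 1) used in the conversion.
    """

    rates: np.ndarray
    weights: np.ndarray
    age_groups: tuple[str, ...] = REPRODUCTIVE_AGE_GROUPS

    def __post_init__(self) -> None:
        rates = np.asarray(self.rates, dtype=float)
        weights = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "rates", rates)
        object.__setattr__(self, "weights", weights)
        if rates.shape != (len(self.age_groups),):
            raise ValueError("one rate per reproductive age group required")
        if np.any(rates < 0):
            raise ValueError("ASFR rates must be non-negative")
        if np.any(weights < 0) or abs(weights.sum() - 1.0) > 1e-6:
            raise ValueError("weights must be non-negative and sum to 1")

    @property
    def tfr(self) -> float:
        return float(5.0 * self.rates.sum())


def default_fertility_priors() -> RegressionPriors:
    """Weakly-informative defaults: N(0, 3^2) on (a, b, c, d), vague gamma on tau."""
    return RegressionPriors(
        curve=tuple(NormalPrior(0.0, 3.0) for _ in range(4)),
        tau=GammaPrior(0.001, 0.001),
    )


def gompertz_mean(t, params: GompertzParams) -> np.ndarray | float:
    """Expected TFR at model time ``t`` (fractional values allowed).

    Monotone in ``t`` for ``b > 0`` and ``c != 0``, running from ``d`` in the
    remote past to ``d + c`` in the remote future.
    """
    t = np.asarray(t, dtype=float)
    with np.errstate(over="ignore", under="ignore"):
        out = params.d + params.c * np.exp(-np.exp(-params.b * (t - params.a)))
    return out if out.ndim else float(out)


def _make_log_posterior(data: TFRSeries, priors: RegressionPriors, weight: float = 1.0):
    y = data.values
    t = data.t_index.astype(float)
    n = len(data)
    locs = np.array([p.loc for p in priors.curve])
    precs = np.array([p.scale for p in priors.curve]) ** -2.0
    a0, b0 = priors.tau.shape, priors.tau.rate

    def log_post(theta: np.ndarray) -> float:
        a, b, c, d, tau = theta
        if tau <= 0:
            return -np.inf
        mu = d + c * np.exp(-np.exp(-b * (t - a)))
        r = y - mu
        ssr = r @ r
        ll = 0.5 * n * math.log(tau) - 0.5 * tau * ssr
        z = theta[:4] - locs
        lp = -0.5 * float(precs @ (z * z)) + (a0 - 1.0) * math.log(tau) - b0 * tau
        return weight * ll + lp

    def ssr_of(theta: np.ndarray) -> float:
        a, b, c, d = theta[:4]
        mu = d + c * np.exp(-np.exp(-b * (t - a)))
        r = y - mu
        return float(r @ r)

    return log_post, ssr_of


def fertility_log_posterior(
    params: GompertzParams,
    data: TFRSeries,
    priors: RegressionPriors | None = None,
) -> float:
    """Log posterior density (up to an additive constant) of the TFR model.

    Gaussian likelihood around the Gompertz mean plus the log prior; returns
    ``-inf`` (rather than raising) when ``tau <= 0``.
    """
    priors = priors or default_fertility_priors()
    log_post, _ = _make_log_posterior(data, priors)
    return log_post(params.as_array())


def _crude_inits(data: TFRSeries, n_chains: int) -> np.ndarray:
    """Moment-based starting values, over-dispersed across chains.

    The crude estimate reads the early level from the first observation, the
    span from the observed decline, the rate from the series length, and the
    precision from the residuals of a straight-line fit.  Chain ``k`` scales
    the curve parameters by alternating factors 1, 1.5, 1/1.5, 1.5^2, ... so
    that chains start over-dispersed but deterministically.
    """
    y = data.values
    n = len(data)
    t = data.t_index.astype(float)
    slope, intercept = np.polyfit(t, y, 1)
    resid = y - (slope * t + intercept)
    var = max(float(resid.var(ddof=1)), 1e-4)
    crude = np.array(
        [n / 3.0, 2.0 / n, -1.3 * (y[0] - y[-1]), y[0] + 0.1 * (y[0] - y[-1]), 1.0 / var]
    )
    inits = np.empty((n_chains, 5))
    for k in range(n_chains):
        factor = 1.5 ** ((-1) ** (k + 1) * ((k + 1) // 2))
        inits[k] = crude * factor
    return inits


def _fit_regression(
    log_post,
    ssr_of,
    n_eff: float,
    priors: RegressionPriors,
    inits: np.ndarray,
    config: MCMCConfig,
    names: tuple[str, ...],
) -> ChainSet:
    a0, b0 = priors.tau.shape, priors.tau.rate

    def draw_tau(theta: np.ndarray, rng: np.random.Generator) -> float:
        ssr = ssr_of(theta)
        draw = rng.gamma(a0 + 0.5 * n_eff, 1.0 / (b0 + 0.5 * ssr))
        return max(draw, 1e-300)

    chains = run_sampler(
        log_post, inits, config, param_names=names, gibbs={len(names) - 1: draw_tau}
    )
    rhat = gelman_rubin(chains)
    warn_msgs = []
    bad = [p for p, r in rhat.items() if r >= 1.2]
    if bad:
        msg = (
            "convergence failure: R-hat >= 1.2 for "
            + ", ".join(f"{p} ({rhat[p]:.3f})" for p in bad)
        )
        warnings.warn(msg)
        warn_msgs.append(msg)
    chains = ChainSet(
        draws=chains.draws,
        param_names=chains.param_names,
        acceptance_rates=chains.acceptance_rates,
        seed=chains.seed,
        rhat=rhat,
        warnings=tuple(warn_msgs),
    )
    return chains.with_derived("sigma", lambda d: d[..., names.index("tau")] ** -0.5)


def fit_fertility(
    data: TFRSeries,
    priors: RegressionPriors | None = None,
    mcmc: MCMCConfig | None = None,
    *,
    likelihood_weight: float = 1.0,
) -> ChainSet:
    """Sample the posterior of the Gompertz TFR model.

    Returns post-burn-in draws over ``(a, b, c, d, tau)`` plus the derived
    residual SD ``sigma``.  R-hat per parameter is attached to the result;
    values at or above 1.2 raise a warning and set a flag on the ChainSet,
    but the draws are still returned for inspection.

    ``likelihood_weight`` scales the data's contribution (0 gives a
    prior-only run, useful for validating the sampler).
    """
    if len(data) < 6:
        raise ValueError("at least 6 observations are required")
    priors = priors or default_fertility_priors()
    mcmc = mcmc or MCMCConfig()
    log_post, ssr_full = _make_log_posterior(data, priors, weight=likelihood_weight)
    ssr_of = (lambda th: likelihood_weight * ssr_full(th)) if likelihood_weight != 1.0 else ssr_full
    inits = _crude_inits(data, mcmc.n_chains)
    return _fit_regression(
        log_post, ssr_of, likelihood_weight * len(data), priors, inits, mcmc, _PARAM_NAMES
    )


@dataclass(frozen=True)
class ProjectedTrajectories:
    """Per-draw trajectories of a vital rate on a calendar-year grid.

    ``values`` has shape ``(n_draws, n_years)``; ``summary`` carries the
    pointwise median and equal-tailed 95% band.
    """

    years: np.ndarray
    values: np.ndarray
    summary: pd.DataFrame = field(repr=False)


def _summarize_trajectories(years: np.ndarray, values: np.ndarray) -> ProjectedTrajectories:
    q = np.percentile(values, [2.5, 50.0, 97.5], axis=0)
    summary = pd.DataFrame(
        {"year": years, "q2.5": q[0], "median": q[1], "q97.5": q[2]}
    )
    return ProjectedTrajectories(years=years, values=values, summary=summary)


def project_tfr(
    draws: ChainSet,
    target_years: Sequence[int],
    *,
    first_year: int = 1991,
    floor: float = 0.0,
) -> ProjectedTrajectories:
    """Evaluate the fitted Gompertz curve at ``target_years`` for every draw.

    Years are mapped to the model index by ``t = year - first_year + 1``.
    Trajectories are floored at ``floor`` (default 0) so that pathological
    posterior draws cannot produce negative fertility.
    """
    years = np.asarray(target_years, dtype=float)
    if years.size == 0:
        raise ValueError("target_years is empty")
    pooled = draws.pooled()
    if pooled.shape[0] == 0:
        raise ValueError("empty ChainSet")
    t = years - first_year + 1.0
    a = pooled[:, draws.index("a"), None]
    b = pooled[:, draws.index("b"), None]
    c = pooled[:, draws.index("c"), None]
    d = pooled[:, draws.index("d"), None]
    with np.errstate(over="ignore", under="ignore"):
        vals = d + c * np.exp(-np.exp(-b * (t[None, :] - a)))
    vals = np.maximum(vals, floor)
    return _summarize_trajectories(years, vals)


def tfr_to_asfr(tfr: float, pattern: Sequence[float] | np.ndarray) -> ASFRSchedule:
    """Spread a TFR over the seven reproductive age groups.

    ``pattern`` gives each group's share of the TFR; the group's annual rate
    is ``tfr * weight / 5`` (5-year age groups), so five times the summed
    rates recovers the TFR exactly.
    """
    weights = np.asarray(pattern, dtype=float)
    if weights.shape != (len(REPRODUCTIVE_AGE_GROUPS),):
        raise ValueError("pattern must supply one weight per reproductive age group")
    if np.any(weights < 0) or abs(weights.sum() - 1.0) > 1e-6:
        raise ValueError("pattern weights must be non-negative and sum to 1")
    if tfr < 0:
        raise ValueError("TFR must be non-negative")
    rates = tfr * weights / 5.0
    return ASFRSchedule(rates=rates, weights=weights)
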