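"""Logistic model for life expectancy at birth, fitted per sex.

Life expectancy at birth (e0) in a developing country typically rises along
an S-shaped path: slowly while health infrastructure is poor, quickly during
expansion of basic services, then slowly again as it approaches a biological
ceiling.  The observed annual series for one sex is modelled as

    Q_i = p(t_i) + eps_i,      eps_i ~ iid N(0, 1/tau)

with the four-parameter logistic mean

    p(t) = q4 + q1 / (1 + exp(q2 - q3 * t))

where ``q4`` is the baseline (lower asymptote, years), ``q1`` the total rise
so that ``q4 + q1`` is the eventual ceiling, ``q3 > 0`` the rate per year
and ``q2/q3`` the index of the inflection point.  The two sexes are fitted
independently; nothing couples their posteriors.

Priors default to N(0, 100^2) on (q1..q4) — diffuse relative to the scale of
life expectancy in years — and gamma(0.001, 0.001) on the precision.
The sampler is the same Metropolis-within-Gibbs engine used for fertility.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .fertility import ProjectedTrajectories, _fit_regression, _summarize_trajectories
from .mcmc import (
    ChainSet,
    GammaPrior,
    MCMCConfig,
    NormalPrior,
    RegressionPriors,
)

__all__ = [
    "E0Series",
    "LogisticParams",
    "default_mortality_priors",
    "logistic_mean",
    "mortality_log_posterior",
    "fit_mortality",
    "project_e0",
]

_PARAM_NAMES = ("q1", "q2", "q3", "q4", "tau")
SEXES = ("male", "female")


@dataclass(frozen=True)
class E0Series:
    """Annual life-expectancy-at-birth observations for one sex."""

    years: np.ndarray
    values: np.ndarray
    sex: str

    def __post_init__(self) -> None:
        years = np.asarray(self.years, dtype=int)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "values", values)
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}")
        if years.size != values.size:
            raise ValueError("years and values must have equal length")
        if years.size and np.any(np.diff(years) <= 0):
            raise ValueError("years must be strictly increasing")
        if np.any(values <= 30) or np.any(values >= 90):
            raise ValueError("e0 values must lie in (30, 90) years")

    def __len__(self) -> int:
        return self.years.size

    @property
    def t_index(self) -> np.ndarray:
        return np.arange(1, len(self) + 1)

    @property
    def first_year(self) -> int:
        return int(self.years[0])

    def year_to_index(self, year) -> np.ndarray:
        return np.asarray(year, dtype=float) - self.first_year + 1.0


@dataclass(frozen=True)
class LogisticParams:
    """Parameters of the logistic e0 regression (see module docstring)."""

    q1: float
    q2: float
    q3: float
    q4: float
    tau: float

    def __post_init__(self) -> None:
        vals = (self.q1, self.q2, self.q3, self.q4, self.tau)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("logistic parameters must be finite")
        if self.tau <= 0:
            raise ValueError("precision tau must be positive")

    @property
    def sigma(self) -> float:
        return self.tau ** -0.5

    @property
    def ceiling(self) -> float:
        """Eventual life-expectancy level q4 + q1."""
        return self.q4 + self.q1

    def as_array(self) -> np.ndarray:
        return np.array([self.q1, self.q2, self.q3, self.q4, self.tau])


def default_mortality_priors() -> RegressionPriors:
    """Vague defaults on the years scale: N(0, 100^2) on q1..q4, gamma on tau."""
    return RegressionPriors(
        curve=tuple(NormalPrior(0.0, 100.0) for _ in range(4)),
        tau=GammaPrior(0.001, 0.001),
    )


def logistic_mean(t, params: LogisticParams) -> np.ndarray | float:
    """Expected e0 at model time ``t``; rises from near ``q4`` to ``q4 + q1``.

    Monotone increasing for ``q1, q3 > 0`` with inflection at ``t = q2/q3``.
    """
    t = np.asarray(t, dtype=float)
    with np.errstate(over="ignore", under="ignore"):
        out = params.q4 + params.q1 / (1.0 + np.exp(params.q2 - params.q3 * t))
    return out if out.ndim else float(out)


def _make_log_posterior(data: E0Series, priors: RegressionPriors, weight: float = 1.0):
    y = data.values
    t = data.t_index.astype(float)
    n = len(data)
    locs = np.array([p.loc for p in priors.curve])
    precs = np.array([p.scale for p in priors.curve]) ** -2.0
    a0, b0 = priors.tau.shape, priors.tau.rate

    def log_post(theta: np.ndarray) -> float:
        q1, q2, q3, q4, tau = theta
        if tau <= 0:
            return -np.inf
        mu = q4 + q1 / (1.0 + np.exp(q2 - q3 * t))
        r = y - mu
        ssr = r @ r
        ll = 0.5 * n * math.log(tau) - 0.5 * tau * ssr
        z = theta[:4] - locs
        lp = -0.5 * float(precs @ (z * z)) + (a0 - 1.0) * math.log(tau) - b0 * tau
        return weight * ll + lp

    def ssr_of(theta: np.ndarray) -> float:
        q1, q2, q3, q4 = theta[:4]
        mu = q4 + q1 / (1.0 + np.exp(q2 - q3 * t))
        r = y - mu
        return float(r @ r)

    return log_post, ssr_of


def mortality_log_posterior(
    params: LogisticParams,
    data: E0Series,
    priors: RegressionPriors | None = None,
) -> float:
    """Log posterior (up to a constant) of the logistic e0 model; ``-inf``
    when ``tau <= 0``."""
    priors = priors or default_mortality_priors()
    log_post, _ = _make_log_posterior(data, priors)
    return log_post(params.as_array())


def _crude_inits(data: E0Series, n_chains: int) -> np.ndarray:
    y = data.values
    n = len(data)
    t = data.t_index.astype(float)
    rise = max(float(y.max() - y.min()), 0.5)
    slope, intercept = np.polyfit(t, y, 1)
    resid = y - (slope * t + intercept)
    var = max(float(resid.var(ddof=1)), 1e-4)
    q3 = 4.0 / n
    crude = np.array([2.0 * rise, q3 * n / 2.0, q3, float(y.min()), 1.0 / var])
    inits = np.empty((n_chains, 5))
    for k in range(n_chains):
        factor = 1.5 ** ((-1) ** (k + 1) * ((k + 1) // 2))
        inits[k] = crude * factor
    return inits


def fit_mortality(
    data: E0Series,
    priors: RegressionPriors | None = None,
    mcmc: MCMCConfig | None = None,
    *,
    likelihood_weight: float = 1.0,
) -> ChainSet:
    """Sample the posterior of the logistic e0 model for one sex.

    Monitors the five nodes ``q1, q2, q3, q4, tau`` plus the derived
    ``sigma``; diagnostics and failure behaviour are as in
    :func:`bayespop.fertility.fit_fertility`.
    """
    if len(data) < 6:
        raise ValueError("at least 6 observations are required")
    priors = priors or default_mortality_priors()
    mcmc = mcmc or MCMCConfig(n_iter=70_000)
    log_post, ssr_full = _make_log_posterior(data, priors, weight=likelihood_weight)
    ssr_of = (lambda th: likelihood_weight * ssr_full(th)) if likelihood_weight != 1.0 else ssr_full
    inits = _crude_inits(data, mcmc.n_chains)
    return _fit_regression(
        log_post, ssr_of, likelihood_weight * len(data), priors, inits, mcmc, _PARAM_NAMES
    )


def project_e0(
    draws: ChainSet,
    target_years: Sequence[int],
    *,
    first_year: int = 1986,
) -> ProjectedTrajectories:
    """Evaluate the fitted logistic at ``target_years`` for every draw.

    Each trajectory is bounded above by its own ``q4 + q1`` by construction.
    The default anchor places the first observation at 1986 so that a
    21-point annual series ends near 2006; the anchor affects only year
    labels, never the fitted curve.
    """
    years = np.asarray(target_years, dtype=float)
    if years.size == 0:
        raise ValueError("target_years is empty")
    pooled = draws.pooled()
    if pooled.shape[0] == 0:
        raise ValueError("empty ChainSet")
    t = years - first_year + 1.0
    q1 = pooled[:, draws.index("q1"), None]
    q2 = pooled[:, draws.index("q2"), None]
    q3 = pooled[:, draws.index("q3"), None]
    q4 = pooled[:, draws.index("q4"), None]
    with np.errstate(over="ignore", under="ignore"):
        vals = q4 + q1 / (1.0 + np.exp(q2 - q3 * t[None, :]))
    return _summarize_trajectories(years, vals)
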