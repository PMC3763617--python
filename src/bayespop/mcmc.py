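"""Metropolis-within-Gibbs sampler with convergence diagnostics and summaries.

The sampler pairs Gaussian random-walk updates (one parameter at a time, with
step sizes adapted during burn-in towards an acceptance rate of about 0.44)
with optional exact Gibbs draws for parameters whose full conditional is known
in closed form — here the error precision of a nonlinear regression, whose
conditional is gamma.  During the second half of burn-in an additional joint
random-walk proposal is tuned from the empirical covariance of the chain,
which speeds mixing along the strong posterior correlations typical of
growth-curve parameters.  All adaptation is frozen once burn-in ends, so the
retained draws come from a fixed Markov kernel.

Posterior summaries mirror the layout demographers expect from BUGS-style
output: mean, SD, Monte Carlo error of the mean, and equal-tailed
2.5/50/97.5 percentiles per parameter.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MCMCConfig",
    "ChainSet",
    "NormalPrior",
    "GammaPrior",
    "RegressionPriors",
    "run_sampler",
    "gelman_rubin",
    "mc_error",
    "summarize",
    "check_mc_error_rule",
    "hpd_interval",
    "write_summary_csv",
    "write_draws_csv",
]

# Smallest precision the tau Gibbs step will return; gamma draws with a tiny
# shape parameter can underflow to exactly zero, which would make the log
# posterior -inf and wedge the chain.
_TAU_FLOOR = 1e-300


@dataclass(frozen=True)
class MCMCConfig:
    """Run-length and tuning settings for one MCMC fit.

    Two chains, 10,000 burn-in and several tens of thousands of retained
    iterations are the working defaults for the vital-rate models in this
    package.
    """

    n_chains: int = 2
    burn_in: int = 10_000
    n_iter: int = 80_000
    seed: int = 0
    adapt: bool = True
    target_accept: float = 0.44
    thin: int = 1

    def __post_init__(self) -> None:
        if self.n_chains < 2:
            raise ValueError("at least 2 chains are required for diagnostics")
        if self.burn_in < 0:
            raise ValueError("burn_in must be non-negative")
        if self.n_iter < 1_000:
            raise ValueError("n_iter must be at least 1,000")
        if not 0.0 < self.target_accept < 1.0:
            raise ValueError("target_accept must lie in (0, 1)")
        if self.thin < 1 or self.n_iter // self.thin < 1:
            raise ValueError("thin must be a positive integer smaller than n_iter")

    @property
    def n_keep(self) -> int:
        """Retained draws per chain after thinning."""
        return self.n_iter // self.thin


@dataclass(frozen=True)
class ChainSet:
    """Post-burn-in MCMC draws for a fixed parameter vector.

    ``draws`` has shape ``(n_chains, n_iter, n_params)``.  Acceptance rates
    are recorded per chain and parameter for random-walk-updated parameters
    and are NaN for Gibbs-updated or derived ones.
    """

    draws: np.ndarray
    param_names: tuple[str, ...]
    acceptance_rates: np.ndarray
    seed: int
    rhat: Mapping[str, float] | None = None
    warnings: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.draws.ndim != 3:
            raise ValueError("draws must be (n_chains, n_iter, n_params)")
        if self.draws.shape[2] != len(self.param_names):
            raise ValueError("param_names does not match draws")

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def n_iter(self) -> int:
        return self.draws.shape[1]

    def index(self, name: str) -> int:
        return self.param_names.index(name)

    def get(self, name: str) -> np.ndarray:
        """Per-chain draws for one parameter, shape (n_chains, n_iter)."""
        return self.draws[:, :, self.index(name)]

    def pooled(self, name: str | None = None) -> np.ndarray:
        """Draws pooled across chains: (n,) for one parameter or (n, P)."""
        if name is not None:
            return self.get(name).reshape(-1)
        return self.draws.reshape(-1, self.draws.shape[2])

    def with_derived(self, name: str, fn: Callable[[np.ndarray], np.ndarray]) -> "ChainSet":
        """Append a derived parameter computed draw-by-draw from the others."""
        extra = fn(self.draws)[..., None]
        draws = np.concatenate([self.draws, extra], axis=2)
        acc = np.concatenate(
            [self.acceptance_rates, np.full((self.n_chains, 1), np.nan)], axis=1
        )
        return replace(
            self, draws=draws, param_names=self.param_names + (name,), acceptance_rates=acc
        )

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format draws: iteration, chain and one column per parameter."""
        frames = []
        for c in range(self.n_chains):
            df = pd.DataFrame(self.draws[c], columns=list(self.param_names))
            df.insert(0, "chain", c)
            df.insert(0, "iteration", np.arange(self.n_iter))
            frames.append(df)
        return pd.concat(frames, ignore_index=True)


@dataclass(frozen=True)
class NormalPrior:
    loc: float = 0.0
    scale: float = 1.0

    def logpdf(self, x: float) -> float:
        z = (x - self.loc) / self.scale
        return -0.5 * z * z - math.log(self.scale)


@dataclass(frozen=True)
class GammaPrior:
    """Gamma(shape, rate) prior, conventionally vague at (0.001, 0.001)."""

    shape: float = 0.001
    rate: float = 0.001

    def logpdf(self, x: float) -> float:
        if x <= 0:
            return -math.inf
        return (self.shape - 1.0) * math.log(x) - self.rate * x


@dataclass(frozen=True)
class RegressionPriors:
    """Independent priors for a nonlinear regression: normals on the curve
    parameters and a gamma on the error precision tau."""

    curve: tuple[NormalPrior, ...]
    tau: GammaPrior = field(default_factory=GammaPrior)

    def log_density(self, theta: Sequence[float], tau: float) -> float:
        if tau <= 0:
            return -math.inf
        out = self.tau.logpdf(tau)
        for prior, x in zip(self.curve, theta, strict=True):
            out += prior.logpdf(x)
        return out


def _safe_log_post(log_posterior: Callable[[np.ndarray], float], theta: np.ndarray) -> float:
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        val = log_posterior(theta)
    if not np.isfinite(val):
        return -math.inf
    return float(val)


def _run_chain(
    log_posterior: Callable[[np.ndarray], float],
    init: np.ndarray,
    config: MCMCConfig,
    gibbs: Mapping[int, Callable[[np.ndarray, np.random.Generator], float]],
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    n_params = init.size
    rw = [j for j in range(n_params) if j not in gibbs]
    theta = init.astype(float).copy()
    lp = _safe_log_post(log_posterior, theta)
    if not np.isfinite(lp):
        raise ValueError(f"log posterior not finite at initial value {init!r}")

    step = np.maximum(0.1 * np.abs(theta), 0.01)
    n_rw = len(rw)
    joint_scale = 2.38 / math.sqrt(max(n_rw, 1))
    joint_chol: np.ndarray | None = None

    total = config.burn_in + config.n_iter
    out = np.empty((config.n_keep, n_params))
    n_kept = 0
    burn_buffer = np.empty((config.burn_in, n_params)) if config.burn_in else None

    acc = np.zeros(n_params)
    win_acc = np.zeros(n_params)
    win_joint = 0.0
    win_len = 50

    for it in range(total):
        in_burn = it < config.burn_in
        for j in rw:
            prop = theta.copy()
            prop[j] += step[j] * rng.standard_normal()
            lpp = _safe_log_post(log_posterior, prop)
            if math.log(rng.random()) < lpp - lp:
                theta, lp = prop, lpp
                if in_burn:
                    win_acc[j] += 1
                else:
                    acc[j] += 1
        if joint_chol is not None and n_rw > 1:
            prop = theta.copy()
            prop[rw] += joint_scale * (joint_chol @ rng.standard_normal(n_rw))
            lpp = _safe_log_post(log_posterior, prop)
            if math.log(rng.random()) < lpp - lp:
                theta, lp = prop, lpp
                if in_burn:
                    win_joint += 1
        for j, draw_conditional in gibbs.items():
            theta[j] = draw_conditional(theta, rng)
        if gibbs:
            lp = _safe_log_post(log_posterior, theta)

        if in_burn:
            burn_buffer[it] = theta
            if config.adapt and (it + 1) % win_len == 0:
                rates = win_acc / win_len
                step *= np.exp(np.clip(rates - config.target_accept, -0.5, 0.5))
                win_acc[:] = 0.0
                if joint_chol is not None:
                    joint_scale *= math.exp(
                        np.clip(win_joint / win_len - 0.234, -0.5, 0.5)
                    )
                    win_joint = 0.0
            # From mid-burn-in onwards, refresh the joint proposal covariance
            # from the accumulated history every 1,000 iterations.
            if (
                config.adapt
                and n_rw > 1
                and it + 1 >= config.burn_in // 2
                and (it + 1) % 1_000 == 0
            ):
                hist = burn_buffer[(it + 1) // 2 : it + 1][:, rw]
                cov = np.cov(hist, rowvar=False)
                cov += 1e-12 * np.eye(n_rw)
                try:
                    joint_chol = np.linalg.cholesky(cov)
                except np.linalg.LinAlgError:
                    joint_chol = None
        else:
            if (it - config.burn_in) % config.thin == 0 and n_kept < out.shape[0]:
                out[n_kept] = theta
                n_kept += 1

    rates = acc / config.n_iter
    rates[[j for j in gibbs]] = np.nan
    return out, rates


def run_sampler(
    log_posterior: Callable[[np.ndarray], float],
    inits: Sequence[Sequence[float]] | np.ndarray,
    config: MCMCConfig,
    *,
    param_names: Sequence[str] | None = None,
    gibbs: Mapping[int, Callable[[np.ndarray, np.random.Generator], float]] | None = None,
) -> ChainSet:
    """Run ``config.n_chains`` Metropolis-within-Gibbs chains.

    Parameters
    ----------
    log_posterior
        Maps a parameter vector to the log posterior density up to an
        additive constant.  Non-finite values are treated as ``-inf``
        (the proposal is rejected); the *initial* value must be finite.
    inits
        One initial parameter vector per chain; chains should be
        over-dispersed for the convergence diagnostic to be meaningful.
    gibbs
        Optional map from parameter index to a function drawing that
        parameter from its exact full conditional given the current state.
        Gibbs parameters are skipped by the random-walk sweep.

    Each chain draws from an independent generator seeded by
    ``(config.seed, chain_index)``; identical inputs give bit-identical
    output.
    """
    inits = np.atleast_2d(np.asarray(inits, dtype=float))
    if inits.shape[0] != config.n_chains:
        raise ValueError(
            f"need {config.n_chains} initial vectors, got {inits.shape[0]}"
        )
    n_params = inits.shape[1]
    gibbs = dict(gibbs or {})
    if param_names is None:
        param_names = tuple(f"p{j}" for j in range(n_params))
    param_names = tuple(param_names)

    all_draws = np.empty((config.n_chains, config.n_keep, n_params))
    all_rates = np.empty((config.n_chains, n_params))
    for k in range(config.n_chains):
        rng = np.random.default_rng([config.seed, k])
        all_draws[k], all_rates[k] = _run_chain(
            log_posterior, inits[k], config, gibbs, rng
        )
    return ChainSet(
        draws=all_draws,
        param_names=param_names,
        acceptance_rates=all_rates,
        seed=config.seed,
    )


def gelman_rubin(chains: ChainSet, param: str | None = None) -> float | dict[str, float]:
    """Classic Gelman–Rubin potential scale reduction factor.

    Uses the between/within-chain variance comparison
    ``sqrt(((n-1)/n * W + B/n) / W)`` without rank normalization.  Values
    near 1 indicate the chains are sampling the same distribution; 1.1 is
    the conventional alarm threshold.
    """
    if chains.n_chains < 2:
        raise ValueError("Gelman-Rubin requires at least 2 chains")
    if chains.n_iter < 10:
        raise ValueError("chains too short for a meaningful R-hat")
    if param is None:
        return {p: gelman_rubin(chains, p) for p in chains.param_names}
    x = chains.get(param)
    n = x.shape[1]
    within = x.var(axis=1, ddof=1).mean()
    between_over_n = x.mean(axis=1).var(ddof=1)
    if within == 0:
        return 1.0
    return float(math.sqrt(((n - 1) / n * within + between_over_n) / within))


def _batch_means_se(x: np.ndarray) -> float:
    n = x.size
    n_batches = math.ceil(math.sqrt(n))
    batch = n // n_batches
    if batch < 1 or n_batches < 2:
        raise ValueError("chain too short for batch-means MC error")
    means = x[: n_batches * batch].reshape(n_batches, batch).mean(axis=1)
    return float(means.std(ddof=1) / math.sqrt(n_batches))


def mc_error(draws: np.ndarray) -> float:
    """Monte Carlo standard error of the posterior-mean estimate.

    Non-overlapping batch means with ``ceil(sqrt(n))`` batches, computed per
    chain and pooled by root mean square (the pooled mean averages the chain
    means, so its variance is the mean of the per-chain variances divided by
    the number of chains).  Accepts a 1-D array (single chain) or a 2-D
    ``(n_chains, n_iter)`` array.
    """
    x = np.asarray(draws, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    if x.shape[1] < 100:
        raise ValueError("at least 100 draws are required")
    ses = np.array([_batch_means_se(row) for row in x])
    return float(math.sqrt(np.mean(ses**2) / x.shape[0]))


def summarize(chains: ChainSet) -> pd.DataFrame:
    """Posterior summary table: one row per parameter.

    Columns ``mean, sd, mc_error, q2.5, median, q97.5`` over the pooled
    post-burn-in draws; the interval columns are equal-tailed percentiles.
    """
    rows = {}
    for name in chains.param_names:
        per_chain = chains.get(name)
        pooled = per_chain.reshape(-1)
        q = np.percentile(pooled, [2.5, 50.0, 97.5])
        rows[name] = {
            "mean": pooled.mean(),
            "sd": pooled.std(ddof=1),
            "mc_error": mc_error(per_chain),
            "q2.5": q[0],
            "median": q[1],
            "q97.5": q[2],
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "node"
    return out


def check_mc_error_rule(summary: pd.DataFrame, threshold: float = 0.05) -> pd.Series:
    """Check the stopping rule that the MC error of every parameter is below
    ``threshold`` (default 5%) of its posterior SD.

    Returns a boolean Series per parameter.  A zero posterior SD makes the
    rule vacuous; it passes with a warning.
    """
    sd = summary["sd"]
    ok = summary["mc_error"] < threshold * sd
    degenerate = sd == 0
    if degenerate.any():
        warnings.warn(
            "zero posterior SD for "
            f"{list(summary.index[degenerate])}; MC-error rule passes vacuously"
        )
        ok = ok | degenerate
    return ok


def hpd_interval(draws: np.ndarray, prob: float = 0.95) -> tuple[float, float]:
    """Shortest (highest posterior density) interval containing ``prob`` mass.

    Provided as an extra; the primary summaries use equal-tailed quantiles.
    """
    x = np.sort(np.asarray(draws, dtype=float).reshape(-1))
    n = x.size
    k = max(1, int(math.ceil(prob * n)))
    if k >= n:
        return float(x[0]), float(x[-1])
    widths = x[k:] - x[: n - k]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + k])


def write_summary_csv(summary: pd.DataFrame, path) -> None:
    summary.rename_axis("node").to_csv(path)


def write_draws_csv(chains: ChainSet, path) -> None:
    chains.to_dataframe().to_csv(path, index=False)
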