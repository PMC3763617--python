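"""Cohort-component projection engine on 5-year age groups and steps.

One projection step advances an age-sex population five years: each closed
cohort is carried into the next group by its survivorship ratio, the two
oldest groups pool into the open 80+ interval, births over the step are
computed by applying age-specific fertility rates to the mid-period female
population, split by the sex ratio at birth, survived into the 0-4 group,
and net migration (zero by default — a closed population) is added.

Posterior uncertainty is propagated by running the engine once per retained
posterior draw: a fertility draw fixes the TFR path, a mortality draw per
sex fixes the e0 path (expanded into survivorship through the relational
life-table system), and the resulting ensemble of trajectories yields
pointwise median and 95% interval forecasts for every age group, sex and
projection year.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .fertility import ASFRSchedule, gompertz_mean, GompertzParams
from .lifetable import (
    StandardSchedule,
    SurvivalRatios,
    brass_logit,
    build_abridged,
    match_e0,
    survival_ratios,
)
from .mcmc import ChainSet
from .mortality import LogisticParams, logistic_mean

__all__ = [
    "AGE_GROUPS",
    "REPRODUCTIVE_INDICES",
    "AgeSexPopulation",
    "ProjectionConfig",
    "ProjectionResult",
    "ValidationReport",
    "births",
    "split_births",
    "project_step",
    "project",
    "validate_projection_table",
]

AGE_GROUPS: tuple[str, ...] = (
    "0-4",
    "5-9",
    "10-14",
    "15-19",
    "20-24",
    "25-29",
    "30-34",
    "35-39",
    "40-44",
    "45-49",
    "50-54",
    "55-59",
    "60-64",
    "65-69",
    "70-74",
    "75-79",
    "80+",
)
N_GROUPS = len(AGE_GROUPS)
# Positions of the reproductive groups 15-19 ... 45-49 within AGE_GROUPS.
REPRODUCTIVE_INDICES = slice(3, 10)


@dataclass(frozen=True)
class AgeSexPopulation:
    """Population counts (thousands) by 5-year age group and sex."""

    reference_year: int
    male: np.ndarray
    female: np.ndarray

    def __post_init__(self) -> None:
        male = np.asarray(self.male, dtype=float)
        female = np.asarray(self.female, dtype=float)
        object.__setattr__(self, "male", male)
        object.__setattr__(self, "female", female)
        for arr, label in ((male, "male"), (female, "female")):
            if arr.shape != (N_GROUPS,):
                raise ValueError(f"{label} counts must cover the {N_GROUPS} age groups")
            if np.any(arr < 0):
                raise ValueError(f"{label} counts must be non-negative")

    def by_sex(self, sex: str) -> np.ndarray:
        return {"male": self.male, "female": self.female}[sex]

    @property
    def total_male(self) -> float:
        return float(self.male.sum())

    @property
    def total_female(self) -> float:
        return float(self.female.sum())

    @property
    def total(self) -> float:
        return self.total_male + self.total_female

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "age_group": list(AGE_GROUPS) * 2,
                "sex": ["male"] * N_GROUPS + ["female"] * N_GROUPS,
                "population_thousands": np.concatenate([self.male, self.female]),
            }
        )


@dataclass(frozen=True)
class ProjectionConfig:
    """Settings of the cohort-component run.

    ``srb`` is male births per 100 female births.  ``net_migration`` maps
    sex to a per-age-group net flow (thousands per 5-year step); the default
    of None means a closed population.
    """

    horizon_year: int
    step: int = 5
    srb: float = 105.0
    net_migration: Mapping[str, np.ndarray] | None = None

    def __post_init__(self) -> None:
        if self.step != 5:
            raise ValueError("only 5-year projection steps are supported")
        if self.srb <= 0:
            raise ValueError("sex ratio at birth must be positive")


def births(
    female_pop_start: np.ndarray,
    female_pop_end: np.ndarray,
    asfr: ASFRSchedule,
    step: int = 5,
) -> float:
    """Total births over one step from mid-period female exposure.

    ``B = step * sum_g ASFR_g * (F_g(t) + F_g(t+step)) / 2`` over the
    reproductive groups.
    """
    start = np.asarray(female_pop_start, dtype=float)
    end = np.asarray(female_pop_end, dtype=float)
    if start.shape != (N_GROUPS,) or end.shape != (N_GROUPS,):
        raise ValueError("female populations must cover all age groups")
    if np.any(start < 0) or np.any(end < 0):
        raise ValueError("populations must be non-negative")
    exposure = 0.5 * (start[REPRODUCTIVE_INDICES] + end[REPRODUCTIVE_INDICES])
    return float(step * np.sum(asfr.rates * exposure))


def split_births(total_births: float, srb: float = 105.0) -> tuple[float, float]:
    """Split births into (male, female) by the sex ratio at birth.

    ``srb`` male births per 100 female births; the two parts sum exactly to
    the input.
    """
    if srb <= 0:
        raise ValueError("sex ratio at birth must be positive")
    if total_births < 0:
        raise ValueError("births must be non-negative")
    male = total_births * srb / (100.0 + srb)
    return male, total_births - male


def _advance_sex(pop: np.ndarray, surv: SurvivalRatios) -> np.ndarray:
    """Survivorship-only pass: age every cohort one group, no births yet."""
    out = np.zeros_like(pop)
    out[1:-1] = pop[:-2] * surv.S
    out[-1] = (pop[-2] + pop[-1]) * surv.S_open
    return out


def project_step(
    pop: AgeSexPopulation,
    survival: Mapping[str, SurvivalRatios],
    asfr: ASFRSchedule,
    config: ProjectionConfig,
) -> AgeSexPopulation:
    """Advance the population one 5-year step.

    Closed cohorts move up one group under their survivorship ratio; the
    75-79 and 80+ groups pool into 80+ under the open-interval ratio;
    births (from mid-period female exposure) are split by the sex ratio at
    birth and survived into 0-4; net migration is added last.
    """
    survived = {s: _advance_sex(pop.by_sex(s), survival[s]) for s in ("male", "female")}
    total = births(pop.female, survived["female"], asfr, step=config.step)
    b_male, b_female = split_births(total, config.srb)
    survived["male"][0] = b_male * survival["male"].S_birth
    survived["female"][0] = b_female * survival["female"].S_birth
    if config.net_migration is not None:
        for s in ("male", "female"):
            survived[s] = np.maximum(survived[s] + np.asarray(config.net_migration[s], float), 0.0)
    return AgeSexPopulation(
        reference_year=pop.reference_year + config.step,
        male=survived["male"],
        female=survived["female"],
    )


@dataclass(frozen=True)
class ProjectionResult:
    """Ensemble of projected populations and their quantile summary.

    ``draws`` has shape ``(n_draws, n_years, 2, n_groups)`` with sex axis
    ordered (male, female); ``years`` are the projected years
    ``base+5 ... horizon``.
    """

    base: AgeSexPopulation
    years: np.ndarray
    draws: np.ndarray
    summary: pd.DataFrame = field(repr=False)

    def population_at(self, draw: int, year: int) -> AgeSexPopulation:
        j = int(np.where(self.years == year)[0][0])
        return AgeSexPopulation(
            reference_year=year, male=self.draws[draw, j, 0], female=self.draws[draw, j, 1]
        )

    def median_table(self) -> pd.DataFrame:
        """Wide age x year table of median counts, in the printed layout:
        an all-ages block (persons/male/female) then per-age sex rows."""
        med = np.median(self.draws, axis=0)  # (n_years, 2, G)
        years = [self.base.reference_year] + [int(y) for y in self.years]
        data: dict[tuple[str, str], list[float]] = {}
        for label in ("persons", "male", "female"):
            data[("all_ages", label)] = []
        for g in AGE_GROUPS:
            data[(g, "male")] = []
            data[(g, "female")] = []
        for j, year in enumerate(years):
            if j == 0:
                m, f = self.base.male, self.base.female
            else:
                m, f = med[j - 1, 0], med[j - 1, 1]
            data[("all_ages", "persons")].append(m.sum() + f.sum())
            data[("all_ages", "male")].append(m.sum())
            data[("all_ages", "female")].append(f.sum())
            for i, g in enumerate(AGE_GROUPS):
                data[(g, "male")].append(m[i])
                data[(g, "female")].append(f[i])
        records = [
            {"age_group": k[0], "sex": k[1], **{str(y): v for y, v in zip(years, vals)}}
            for k, vals in data.items()
        ]
        return pd.DataFrame.from_records(records)


def _quantile_summary(
    years: np.ndarray, draws: np.ndarray
) -> pd.DataFrame:
    q = np.percentile(draws, [2.5, 50.0, 97.5], axis=0)  # (3, n_years, 2, G)
    rows = []
    for j, year in enumerate(years):
        for s_idx, sex in enumerate(("male", "female")):
            for i, g in enumerate(AGE_GROUPS):
                rows.append(
                    {
                        "year": int(year),
                        "age_group": g,
                        "sex": sex,
                        "q2.5": q[0, j, s_idx, i],
                        "median": q[1, j, s_idx, i],
                        "q97.5": q[2, j, s_idx, i],
                    }
                )
    return pd.DataFrame.from_records(rows)


def _params_from_draw(pooled: np.ndarray, names: Sequence[str], cls):
    kwargs = {n: float(v) for n, v in zip(names, pooled)}
    kwargs.pop("sigma", None)
    return cls(**kwargs)


def project(
    base: AgeSexPopulation,
    fertility_draws: ChainSet,
    mortality_draws: Mapping[str, ChainSet],
    config: ProjectionConfig,
    seed: int,
    *,
    asfr_pattern: np.ndarray,
    standards: Mapping[str, StandardSchedule],
    n_trajectories: int = 500,
    fert_first_year: int = 1991,
    mort_first_year: int = 1986,
) -> ProjectionResult:
    """Propagate posterior draws through the cohort-component engine.

    For each of ``n_trajectories`` randomly paired posterior draws (one
    fertility draw, one mortality draw per sex — the components were fitted
    independently, so pairing is random with the given ``seed``), the TFR
    and e0 curves are evaluated at each step's midpoint year, converted to
    an ASFR schedule and per-sex survivorship ratios, and the population is
    stepped from the base year to the horizon.  Pointwise 2.5/50/97.5
    percentiles across trajectories summarize the uncertainty.

    Draw-specific e0 values falling outside the span achievable by the
    relational life-table system are clipped to its boundary.
    """
    if (config.horizon_year - base.reference_year) % config.step != 0:
        raise ValueError("horizon must be a whole number of steps from the base year")
    n_steps = (config.horizon_year - base.reference_year) // config.step
    if n_steps < 1:
        raise ValueError("horizon must lie after the base year")

    rng = np.random.default_rng([seed, 0x5EED])
    fert_pool = fertility_draws.pooled()
    pools = {s: mortality_draws[s].pooled() for s in ("male", "female")}
    n = min(n_trajectories, fert_pool.shape[0], *(p.shape[0] for p in pools.values()))
    if n < 1:
        raise ValueError("no posterior draws available")
    fert_idx = rng.permutation(fert_pool.shape[0])[:n]
    mort_idx = {s: rng.permutation(pools[s].shape[0])[:n] for s in ("male", "female")}

    # Life-table construction is the expensive inner step; cache survivorship
    # ratios on a 0.01-year e0 grid (the match_e0 tolerance).
    surv_cache: dict[tuple[str, float], SurvivalRatios] = {}
    e0_bounds = {}
    for s in ("male", "female"):
        std = standards[s]
        hi = build_abridged(brass_logit(std.lx, -2.0), std.m80).e0
        lo = build_abridged(brass_logit(std.lx, 2.0), std.m80).e0
        e0_bounds[s] = (lo + 0.02, hi - 0.02)

    def surv_for(sex: str, e0: float) -> SurvivalRatios:
        lo, hi = e0_bounds[sex]
        key = (sex, round(min(max(e0, lo), hi), 2))
        if key not in surv_cache:
            surv_cache[key] = survival_ratios(match_e0(key[1], standards[sex]))
        return surv_cache[key]

    years = base.reference_year + config.step * np.arange(1, n_steps + 1)
    mids = years - config.step / 2.0  # midpoint of each step interval
    out = np.empty((n, n_steps, 2, N_GROUPS))
    fert_names = fertility_draws.param_names
    mort_names = {s: mortality_draws[s].param_names for s in ("male", "female")}

    for k in range(n):
        gp = _params_from_draw(fert_pool[fert_idx[k]], fert_names, GompertzParams)
        lp = {
            s: _params_from_draw(pools[s][mort_idx[s][k]], mort_names[s], LogisticParams)
            for s in ("male", "female")
        }
        pop = base
        for j, (year, mid) in enumerate(zip(years, mids)):
            tfr = max(float(gompertz_mean(mid - fert_first_year + 1.0, gp)), 0.0)
            asfr = ASFRSchedule(rates=tfr * asfr_pattern / 5.0, weights=asfr_pattern)
            survival = {
                s: surv_for(s, float(logistic_mean(mid - mort_first_year + 1.0, lp[s])))
                for s in ("male", "female")
            }
            pop = project_step(pop, survival, asfr, config)
            out[k, j, 0] = pop.male
            out[k, j, 1] = pop.female

    return ProjectionResult(
        base=base, years=years, draws=out, summary=_quantile_summary(years, out)
    )


@dataclass(frozen=True)
class ValidationReport:
    """Outcome of the internal-consistency checks on a projection table."""

    checks: pd.DataFrame

    @property
    def ok(self) -> bool:
        return bool(self.checks["ok"].all())

    @property
    def violations(self) -> pd.DataFrame:
        return self.checks[~self.checks["ok"]]


def validate_projection_table(table: pd.DataFrame, tol: float = 2.0) -> ValidationReport:
    """Check the bookkeeping identities of an age-sex projection table.

    ``table`` is the wide layout: columns ``age_group``, ``sex`` and one
    column per year; ``age_group == 'all_ages'`` rows carry the totals, with
    ``sex`` in {persons, male, female}.  Two identities are checked per
    year: persons = male + female among the all-ages rows, and the per-sex
    age-group sum equals the all-ages total.  ``tol`` (thousands) absorbs
    rounding in printed tables.
    """
    required = {"age_group", "sex"}
    if not required.issubset(table.columns):
        raise ValueError("table must have age_group and sex columns")
    year_cols = [c for c in table.columns if c not in required]
    if not year_cols:
        raise ValueError("table has no year columns")
    totals = table[table["age_group"] == "all_ages"].set_index("sex")
    by_age = table[table["age_group"] != "all_ages"]
    rows = []
    for y in year_cols:
        if {"persons", "male", "female"}.issubset(totals.index):
            diff = totals.loc["persons", y] - totals.loc["male", y] - totals.loc["female", y]
            rows.append(
                {
                    "year": y,
                    "check": "persons = male + female",
                    "sex": "persons",
                    "diff": float(diff),
                    "ok": abs(diff) <= tol,
                }
            )
        for s in ("male", "female"):
            if s in totals.index:
                diff = by_age[by_age["sex"] == s][y].sum() - totals.loc[s, y]
                rows.append(
                    {
                        "year": y,
                        "check": "age-group sum = all-ages total",
                        "sex": s,
                        "diff": float(diff),
                        "ok": abs(diff) <= tol,
                    }
                )
    return ValidationReport(checks=pd.DataFrame.from_records(rows))
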