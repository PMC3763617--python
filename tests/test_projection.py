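"""Cohort-component engine: births, stepping, uncertainty propagation and
table validation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import bayespop as bp
from bayespop.projection import AGE_GROUPS, N_GROUPS, REPRODUCTIVE_INDICES

from _oracles import leslie_matrix
from conftest import make_chainset


def uniform_asfr(tfr: float) -> bp.ASFRSchedule:
    return bp.tfr_to_asfr(tfr, np.full(7, 1 / 7))


def ratios(s_birth, closed, s_open) -> bp.SurvivalRatios:
    return bp.SurvivalRatios(S_birth=s_birth, S=np.asarray(closed, float), S_open=s_open)


def random_instance(rng):
    pop = bp.AgeSexPopulation(
        reference_year=2001,
        male=rng.uniform(10, 1_000, N_GROUPS),
        female=rng.uniform(10, 1_000, N_GROUPS),
    )
    surv = {
        s: ratios(rng.uniform(0.9, 1.0), rng.uniform(0.5, 1.0, 15), rng.uniform(0.3, 0.9))
        for s in ("male", "female")
    }
    pattern = rng.dirichlet(np.ones(7))
    asfr = bp.tfr_to_asfr(rng.uniform(0.5, 6.0), pattern)
    return pop, surv, asfr


class TestBirths:
    def test_zero_rates_no_births(self):
        f = np.full(N_GROUPS, 100.0)
        assert bp.births(f, f, uniform_asfr(0.0)) == 0.0

    def test_single_group_arithmetic(self):
        rates = np.zeros(7)
        rates[1] = 0.1  # group 20-24
        sched = bp.ASFRSchedule(rates=rates, weights=np.full(7, 1 / 7))
        f = np.zeros(N_GROUPS)
        f[4] = 1_000.0  # 20-24 is the 5th group overall
        assert bp.births(f, f, sched) == pytest.approx(500.0)

    @given(scale=st.floats(0.1, 10.0))
    def test_linearity_in_female_population(self, scale):
        rng = np.random.default_rng(0)
        f1 = rng.uniform(10, 500, N_GROUPS)
        f2 = rng.uniform(10, 500, N_GROUPS)
        asfr = uniform_asfr(3.0)
        assert bp.births(scale * f1, scale * f2, asfr) == pytest.approx(
            scale * bp.births(f1, f2, asfr), rel=1e-12
        )

    def test_negative_population_rejected(self):
        f = np.full(N_GROUPS, -1.0)
        with pytest.raises(ValueError):
            bp.births(f, f, uniform_asfr(2.0))


class TestSplitBirths:
    def test_published_ratio_example(self):
        assert bp.split_births(205.0, srb=105.0) == (105.0, 100.0)

    def test_zero_births(self):
        assert bp.split_births(0.0) == (0.0, 0.0)

    @given(total=st.floats(0.0, 1e6), srb=st.floats(50.0, 150.0))
    def test_conservation(self, total, srb):
        m, f = bp.split_births(total, srb)
        assert m + f == pytest.approx(total, abs=1e-12 * max(total, 1.0))
        assert m >= 0 and f >= 0

    def test_invalid_srb_rejected(self):
        with pytest.raises(ValueError):
            bp.split_births(100.0, srb=0.0)


class TestProjectStep:
    def test_pure_transport_conserves_total(self, base_population):
        surv = {s: ratios(1.0, np.ones(15), 1.0) for s in ("male", "female")}
        cfg = bp.ProjectionConfig(horizon_year=2006)
        out = bp.project_step(base_population, surv, uniform_asfr(0.0), cfg)
        assert out.total == pytest.approx(base_population.total, abs=1e-9)
        # every cohort shifts one group up, accumulating at 80+
        assert np.allclose(out.male[1:-1], base_population.male[:-2])
        assert out.male[-1] == pytest.approx(
            base_population.male[-2] + base_population.male[-1]
        )
        assert out.male[0] == 0.0

    def test_matches_leslie_matrix_oracle(self):
        rng = np.random.default_rng(7)
        cfg = bp.ProjectionConfig(horizon_year=2006)
        for _ in range(200):
            pop, surv, asfr = random_instance(rng)
            stepped = bp.project_step(pop, surv, asfr, cfg)
            A = leslie_matrix(
                (surv["male"].S_birth, surv["male"].S, surv["male"].S_open),
                (surv["female"].S_birth, surv["female"].S, surv["female"].S_open),
                asfr.rates,
                srb=cfg.srb,
            )
            expected = A @ np.concatenate([pop.male, pop.female])
            got = np.concatenate([stepped.male, stepped.female])
            assert np.allclose(got, expected, atol=1e-9, rtol=0)

    def test_survivors_never_exceed_parent_cohort(self):
        rng = np.random.default_rng(8)
        pop, surv, asfr = random_instance(rng)
        cfg = bp.ProjectionConfig(horizon_year=2006)
        out = bp.project_step(pop, surv, asfr, cfg)
        assert np.all(out.male[1:-1] <= pop.male[:-2] + 1e-12)
        assert np.all(out.female[1:-1] <= pop.female[:-2] + 1e-12)

    def test_monotone_response_to_survival(self):
        rng = np.random.default_rng(9)
        pop, surv, asfr = random_instance(rng)
        cfg = bp.ProjectionConfig(horizon_year=2006)
        lo = bp.project_step(pop, surv, asfr, cfg)
        boosted = {
            s: ratios(
                min(1.0, surv[s].S_birth * 1.05),
                np.minimum(1.0, surv[s].S * 1.05),
                min(1.0, surv[s].S_open * 1.05),
            )
            for s in ("male", "female")
        }
        hi = bp.project_step(pop, boosted, asfr, cfg)
        assert np.all(hi.male >= lo.male - 1e-12)
        assert np.all(hi.female >= lo.female - 1e-12)

    def test_net_migration_added(self, base_population):
        surv = {s: ratios(1.0, np.ones(15), 1.0) for s in ("male", "female")}
        mig = {s: np.full(N_GROUPS, 10.0) for s in ("male", "female")}
        cfg = bp.ProjectionConfig(horizon_year=2006, net_migration=mig)
        out = bp.project_step(base_population, surv, uniform_asfr(0.0), cfg)
        assert out.total == pytest.approx(base_population.total + 2 * 10.0 * N_GROUPS)

    def test_invalid_survival_rejected(self):
        with pytest.raises(ValueError):
            ratios(1.0, np.ones(15) * 1.5, 1.0)
        with pytest.raises(ValueError):
            ratios(0.0, np.ones(15), 1.0)


def small_posterior_chainsets(e0_male=62.0, e0_female=64.0, jitter=0.0, n=5):
    """Hand-made posterior ensembles with n identical (or jittered) draws."""
    rng = np.random.default_rng(0)
    fert = np.tile(np.array([3.6, 0.19, -3.49, 5.058, 100.0, 0.1]), (1, n, 1))
    fert_chain = make_chainset(fert, ("a", "b", "c", "d", "tau", "sigma"))
    mort = {}
    for sex, e0 in (("male", e0_male), ("female", e0_female)):
        # q1 = 0 makes the curve flat at q4 = e0 for all years
        draw = np.tile(np.array([0.0, 1.0, 0.1, e0, 4.0, 0.5]), (1, n, 1))
        if jitter:
            draw = draw + rng.normal(0, jitter, draw.shape) * np.array([0, 0, 0, 1, 0, 0])
        mort[sex] = make_chainset(draw, ("q1", "q2", "q3", "q4", "tau", "sigma"))
    return fert_chain, mort


class TestProject:
    def test_single_draw_quantiles_collapse(self, base_population, standards, asfr_pattern):
        fert, mort = small_posterior_chainsets(n=1)
        res = bp.project(
            base_population,
            fert,
            mort,
            bp.ProjectionConfig(horizon_year=2016),
            seed=1,
            asfr_pattern=asfr_pattern,
            standards=standards,
            n_trajectories=1,
        )
        assert np.allclose(res.summary["q2.5"], res.summary["q97.5"])
        assert np.allclose(res.summary["q2.5"], res.summary["median"])

    def test_zero_fertility_population_shrinks(self, base_population, standards, asfr_pattern):
        fert_draw = np.tile(np.array([3.6, 0.19, 0.0, 0.0, 100.0, 0.1]), (1, 3, 1))
        fert = make_chainset(fert_draw, ("a", "b", "c", "d", "tau", "sigma"))
        _, mort = small_posterior_chainsets(n=3)
        res = bp.project(
            base_population,
            fert,
            mort,
            bp.ProjectionConfig(horizon_year=2021),
            seed=2,
            asfr_pattern=asfr_pattern,
            standards=standards,
            n_trajectories=3,
        )
        totals = res.draws.sum(axis=(2, 3))
        assert np.all(totals[:, -1] <= base_population.total)
        assert np.all(np.diff(totals, axis=1) <= 0)

    def test_sex_totals_sum_to_persons(self, base_population, standards, asfr_pattern):
        fert, mort = small_posterior_chainsets(jitter=0.5, n=8)
        res = bp.project(
            base_population,
            fert,
            mort,
            bp.ProjectionConfig(horizon_year=2021),
            seed=3,
            asfr_pattern=asfr_pattern,
            standards=standards,
            n_trajectories=8,
        )
        persons = res.draws.sum(axis=(2, 3))
        by_sex = res.draws.sum(axis=3)
        assert np.allclose(persons, by_sex[:, :, 0] + by_sex[:, :, 1], atol=1e-9)

    def test_deterministic_given_seed(self, base_population, standards, asfr_pattern):
        fert, mort = small_posterior_chainsets(jitter=0.5, n=8)
        kwargs = dict(
            asfr_pattern=asfr_pattern, standards=standards, n_trajectories=4
        )
        cfg = bp.ProjectionConfig(horizon_year=2016)
        r1 = bp.project(base_population, fert, mort, cfg, seed=11, **kwargs)
        r2 = bp.project(base_population, fert, mort, cfg, seed=11, **kwargs)
        assert np.array_equal(r1.draws, r2.draws)

    def test_misaligned_horizon_rejected(self, base_population, standards, asfr_pattern):
        fert, mort = small_posterior_chainsets()
        with pytest.raises(ValueError):
            bp.project(
                base_population,
                fert,
                mort,
                bp.ProjectionConfig(horizon_year=2019),
                seed=0,
                asfr_pattern=asfr_pattern,
                standards=standards,
            )

    def test_median_table_layout(self, base_population, standards, asfr_pattern):
        fert, mort = small_posterior_chainsets(n=2)
        res = bp.project(
            base_population,
            fert,
            mort,
            bp.ProjectionConfig(horizon_year=2011),
            seed=5,
            asfr_pattern=asfr_pattern,
            standards=standards,
            n_trajectories=2,
        )
        table = res.median_table()
        assert set(table.columns) == {"age_group", "sex", "2001", "2006", "2011"}
        report = bp.validate_projection_table(table, tol=1e-6)
        assert report.ok


class TestValidateProjectionTable:
    def test_published_base_column_identities(self, published_table):
        base = published_table[published_table["age_group"] != "all_ages"]
        male_sum = base[base["sex"] == "male"]["2001"].sum()
        female_sum = base[base["sex"] == "female"]["2001"].sum()
        assert male_sum == 63_895
        assert female_sum == 59_956
        totals = published_table[published_table["age_group"] == "all_ages"].set_index("sex")
        assert totals.loc["persons", "2001"] == 123_851
        assert male_sum + female_sum == totals.loc["persons", "2001"]

    def test_published_2006_total_identity(self, published_table):
        totals = published_table[published_table["age_group"] == "all_ages"].set_index("sex")
        assert totals.loc["male", "2006"] + totals.loc["female", "2006"] == 133_436
        assert totals.loc["persons", "2006"] == 133_436

    def test_full_published_table_passes(self, published_table):
        report = bp.validate_projection_table(published_table, tol=2.0)
        assert report.ok

    def test_corrupted_cell_flagged_locally(self, published_table):
        bad = published_table.copy()
        idx = bad[(bad["age_group"] == "20-24") & (bad["sex"] == "male")].index[0]
        bad.loc[idx, "2011"] += 50
        report = bp.validate_projection_table(bad, tol=2.0)
        assert not report.ok
        v = report.violations
        assert set(v["year"]) == {"2011"}
        assert set(v["sex"]) == {"male"}
        # all other year columns still pass
        ok_years = report.checks[report.checks["ok"]]["year"]
        assert "2006" in set(ok_years)

    def test_structural_mismatch_rejected(self):
        with pytest.raises(ValueError):
            bp.validate_projection_table(pd.DataFrame({"foo": [1]}))


class TestAgeSexPopulation:
    def test_persons_identity(self, base_population):
        assert base_population.total == pytest.approx(
            base_population.total_male + base_population.total_female, abs=1e-9
        )

    def test_seventeen_groups_enforced(self):
        with pytest.raises(ValueError):
            bp.AgeSexPopulation(2001, np.ones(16), np.ones(17))

    def test_negative_counts_rejected(self):
        bad = np.ones(N_GROUPS)
        bad[3] = -1
        with pytest.raises(ValueError):
            bp.AgeSexPopulation(2001, bad, np.ones(N_GROUPS))

    def test_reproductive_slice_matches_labels(self):
        assert AGE_GROUPS[REPRODUCTIVE_INDICES] == (
            "15-19",
            "20-24",
            "25-29",
            "30-34",
            "35-39",
            "40-44",
            "45-49",
        )
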