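"""Unit and property tests for the agent-based population simulator."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

import cyclefate as cf
from cyclefate.cellsim import (
    STATE_CYCLING,
    STATE_DIFFERENTIATED,
    Population,
    step,
)
from cyclefate.errors import InvalidConfigError, InvalidParameterError


class TestCycleLengthDraw:
    def test_zero_cv_is_degenerate(self):
        rng = np.random.default_rng(0)
        assert cf.draw_cycle_length(20.0, 0.0, rng) == 20.0

    def test_gamma_moments(self):
        # mean 20, sd 6 for cv=0.3; 1e5 draws pin both to ~1% accuracy
        rng = np.random.default_rng(1)
        draws = cf.draw_cycle_length(20.0, 0.3, rng, size=100_000)
        assert abs(draws.mean() - 20.0) < 0.06
        assert abs(draws.std(ddof=1) - 6.0) < 0.1
        assert np.all(draws > 0)

    @pytest.mark.parametrize("mean", [0.0, -5.0])
    def test_nonpositive_mean_rejected(self, mean):
        with pytest.raises(InvalidParameterError):
            cf.draw_cycle_length(mean, 0.3, np.random.default_rng(0))


class TestInitPopulation:
    def test_full_growth_fraction_all_cycling(self):
        cfg = cf.SimConfig(initial_count=10, seed=0)
        pop = cf.init_population(cfg)
        assert len(pop) == 10
        assert np.all(pop.state == STATE_CYCLING)
        assert np.all((0 <= pop.age) & (pop.age < pop.cycle_length))

    def test_empty_population_runs_to_zero_rows(self):
        counts = cf.run(cf.SimConfig(initial_count=0, t_end=5.0, seed=0))
        assert (counts.frame[["P", "D", "Q", "A"]].to_numpy() == 0).all()

    def test_quiescent_fraction_binomial(self):
        m, g = 10_000, 0.5
        cfg = cf.SimConfig(
            initial_count=m, seed=2, schedules=cf.ScheduleSet(gamma=cf.constant(g))
        )
        pop = cf.init_population(cfg)
        q = int((pop.state == 1).sum())
        sd = np.sqrt(m * g * (1 - g))
        assert abs(q - m * (1 - g)) < 3 * sd

    def test_negative_count_rejected(self):
        with pytest.raises(InvalidConfigError):
            cf.SimConfig(initial_count=-1).validate()


class TestDivide:
    def _mother(self):
        return cf.CellRecord(
            id=0, birth_time=0.0, cycle_length=20.0, age=20.0, phase="G2M",
            state="cycling", labels=frozenset({("edu", 3.0)}),
        )

    @pytest.mark.parametrize("ppdd,expected", [(1.0, "cycling"), (-1.0, "differentiated")])
    def test_deterministic_fates(self, ppdd, expected):
        d1, d2 = cf.divide(self._mother(), ppdd, np.random.default_rng(0), 20.0)
        assert d1.state == d2.state == expected
        assert d1.age == d2.age == 0.0
        assert d1.labels == d2.labels == frozenset({("edu", 3.0)})

    def test_pd_fraction_matches_independent_fates(self):
        # p = 0.75 for ppdd = 0.5; pd probability 2p(1-p) = 0.375
        rng = np.random.default_rng(3)
        n = 10_000
        pd_count = 0
        for _ in range(n):
            d1, d2 = cf.divide(self._mother(), 0.5, rng, 20.0)
            if d1.state != d2.state:
                pd_count += 1
        se = np.sqrt(0.375 * 0.625 / n)
        assert abs(pd_count / n - 0.375) < 3 * se

    def test_out_of_range_ppdd_rejected(self):
        with pytest.raises(InvalidParameterError):
            cf.divide(self._mother(), 1.5, np.random.default_rng(0), 20.0)


class TestStep:
    def test_differentiated_population_inert(self):
        pop = Population(
            [STATE_DIFFERENTIATED], [20.0], [5.0], [0.0], [0]
        )
        sched = cf.ScheduleSet()
        for k in range(50):
            step(pop, k * 0.1, 0.1, sched, np.random.default_rng(0))
        assert len(pop) == 1 and pop.state[0] == STATE_DIFFERENTIATED
        assert pop.age[0] == 5.0 and pop.divisions == 0

    def test_division_at_cycle_end(self):
        pop = Population([STATE_CYCLING], [20.0], [20.0 - 0.05], [0.0], [0])
        sched = cf.ScheduleSet(ppdd=cf.constant(1.0))
        step(pop, 0.0, 0.1, sched, np.random.default_rng(0))
        assert len(pop) == 2
        assert np.all(pop.state == STATE_CYCLING)
        assert np.all(pop.age == 0.0)

    def test_apoptosis_hazard_matches_exponential_decay(self):
        # dP/dt = -rate * P at homeostasis (ppdd=0): P(t) = m exp(-rate t)
        rate, m = 0.01, 5000
        sched = cf.ScheduleSet(apoptosis_rate=cf.constant(rate))
        Ps = []
        for ss in np.random.SeedSequence(4).spawn(10):
            cfg = cf.SimConfig(initial_count=m, t_end=48.0, record_interval=12.0,
                               schedules=sched)
            Ps.append(cf.run(cfg, rng=np.random.default_rng(ss)).column("P"))
        mean_P = np.mean(Ps, axis=0)
        t = np.arange(0, 48.1, 12.0)
        expected = m * np.exp(-rate * t)
        assert np.all(np.abs(mean_P - expected) / expected < 0.05)


class TestRun:
    def test_homeostasis_conserves_expected_count(self, homeostatic_config):
        finals = []
        for ss in np.random.SeedSequence(5).spawn(10):
            finals.append(
                cf.run(homeostatic_config, rng=np.random.default_rng(ss)).column("P")[-1]
            )
        se = np.std(finals, ddof=1) / np.sqrt(len(finals))
        assert abs(np.mean(finals) - 500) < 3 * se + 1e-9

    def test_deterministic_doubling_with_fixed_cycle(self):
        # cv=0, uniform ages, ppdd=1: every lineage quadruples by t = 2T
        sched = cf.ScheduleSet(ppdd=cf.constant(1.0), cv=0.0)
        cfg = cf.SimConfig(initial_count=1000, t_end=40.0, seed=6, schedules=sched)
        counts = cf.run(cfg)
        assert counts.column("P")[-1] == 4000

    def test_terminal_divisions_exhaust_progenitors(self):
        sched = cf.ScheduleSet(ppdd=cf.constant(-1.0))
        cfg = cf.SimConfig(initial_count=500, t_end=48.0, seed=7, schedules=sched)
        counts = cf.run(cfg)
        assert counts.column("P")[-1] == 0
        assert counts.column("D")[-1] >= 500
        # growth stops once the progenitor pool is gone
        D = counts.column("D")
        last_change = np.max(np.flatnonzero(np.diff(D) != 0), initial=0)
        assert np.all(np.diff(D)[last_change + 1:] == 0)

    def test_same_seed_bitwise_identical(self):
        cfg = cf.SimConfig(initial_count=300, t_end=24.0, seed=9)
        a = cf.run(cfg).frame
        b = cf.run(cfg).frame
        assert a.equals(b)

    def test_counts_invariants_and_conservation(self, homeostatic_config):
        sched = cf.ScheduleSet(
            ppdd=cf.constant(0.2),
            gamma=cf.constant(0.8),
            apoptosis_rate=cf.constant(0.004),
        )
        cfg = homeostatic_config.with_(schedules=sched, seed=13)
        rng = np.random.default_rng(cfg.seed)
        pop = cf.init_population(cfg, rng)
        m = len(pop)
        n_steps = int(round(cfg.t_end / cfg.dt))
        prev_D = prev_A = 0
        for k in range(n_steps):
            step(pop, k * cfg.dt, cfg.dt, sched, rng)
            if k % 60 == 0:
                row = pop.counts_row((k + 1) * cfg.dt)
                assert row["P"] == row["P_cycling"] + row["Q"]
                assert row["D"] >= prev_D and row["A"] >= prev_A
                prev_D, prev_A = row["D"], row["A"]
                # ledger identities: every division removes 1 and adds 2;
                # alive cells (P incl. Q, plus D) = created - removed
                assert pop.created == m + 2 * pop.divisions
                removed = pop.divisions + pop.apoptotic
                assert row["P"] + row["D"] == pop.created - removed

    def test_homeostasis_null_slope(self):
        # pooled linear trend of P(t) statistically indistinguishable from 0
        runs = []
        for ss in np.random.SeedSequence(15).spawn(10):
            cfg = cf.SimConfig(initial_count=500, t_end=48.0, record_interval=4.0)
            runs.append(cf.run(cfg, rng=np.random.default_rng(ss)).column("P"))
        t = np.arange(0.0, 48.1, 4.0)
        pooled = np.mean(runs, axis=0)
        slope, intercept = np.polyfit(t, pooled, 1)
        resid = pooled - (slope * t + intercept)
        se = np.sqrt(np.sum(resid**2) / (len(t) - 2) / np.sum((t - t.mean()) ** 2))
        assert abs(slope) < 3 * se + 1e-12

    def test_ode_limit(self):
        # mean trajectories track dP/dt = (ppdd*gamma/T - a) P,
        # dD/dt = (1 - ppdd) gamma P / T within 10%
        ppdd, gam, T, a = 0.2, 0.9, 20.0, 0.002
        sched = cf.ScheduleSet(
            T_mean=cf.constant(T), ppdd=cf.constant(ppdd),
            gamma=cf.constant(gam), apoptosis_rate=cf.constant(a),
        )
        m, t_end = 1000, 36.0
        Ps, Ds = [], []
        for ss in np.random.SeedSequence(16).spawn(10):
            cfg = cf.SimConfig(initial_count=m, t_end=t_end, record_interval=6.0,
                               schedules=sched)
            out = cf.run(cfg, rng=np.random.default_rng(ss))
            Ps.append(out.column("P"))
            Ds.append(out.column("D"))
        t_eval = np.arange(0.0, t_end + 0.1, 6.0)
        sol = solve_ivp(
            lambda t, y: [
                (ppdd * gam / T - a) * y[0],
                (1 - ppdd) * gam * y[0] / T,
            ],
            (0, t_end), [m, 0.0], t_eval=t_eval, rtol=1e-9,
        )
        mean_P, mean_D = np.mean(Ps, axis=0), np.mean(Ds, axis=0)
        assert np.all(np.abs(mean_P - sol.y[0]) / sol.y[0] < 0.10)
        assert np.all(np.abs(mean_D[1:] - sol.y[1][1:]) / sol.y[1][1:] < 0.10)


class TestSchedules:
    @given(st.floats(-1, 1), st.floats(0, 1), st.floats(0.1, 100))
    @settings(max_examples=50, derandomize=True)
    def test_constant_schedules_valid(self, ppdd, gamma, T):
        sched = cf.ScheduleSet(
            T_mean=cf.constant(T), ppdd=cf.constant(ppdd), gamma=cf.constant(gamma)
        )
        sched.validate_at(0.0)
        sched.validate_at(17.3)

    def test_invalid_schedule_rejected(self):
        with pytest.raises(InvalidConfigError):
            cf.ScheduleSet(ppdd=cf.constant(1.5)).validate_at(0.0)

    def test_piecewise_linear_interpolates(self):
        f = cf.piecewise_linear([(0.0, 10.0), (10.0, 30.0)])
        assert f(5.0) == 20.0
        assert f(-1.0) == 10.0  # clamped
        assert f(11.0) == 30.0
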