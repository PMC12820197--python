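"""Assemblage dynamics: caps, filtering, reproducibility, and the
species-count scheme against a per-individual oracle."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from thermassembly.environment import EnvironmentConfig, ProductivityModel, carrying_capacity
from thermassembly.simulator import (
    AssemblageState,
    SimulationConfig,
    init_state,
    run_simulation,
    step,
)
from thermassembly.thermal_traits import TraitPrior, make_tpc


def _state_with(cfg, species):
    """Build a state holding the given (tpc, n) species."""
    st = init_state(dataclasses.replace(cfg, n_init=0))
    for tpc, n in species:
        st.add_species(tpc, n)
    return st


class TestInitState:
    def test_empty_when_no_founders(self, quick_config):
        cfg = dataclasses.replace(quick_config, n_init=0)
        assert init_state(cfg).richness == 0

    def test_default_founders_and_cap(self, quick_config):
        st = init_state(quick_config)
        assert st.richness == quick_config.n_init
        assert st.total_abundance <= st.capacity
        assert st.total_abundance == quick_config.n_init * quick_config.n0

    def test_same_seed_same_founders(self, quick_config):
        a, b = init_state(quick_config), init_state(quick_config)
        assert np.array_equal(a.ctmin, b.ctmin)
        assert np.array_equal(a.ctmax, b.ctmax)

    def test_zero_capacity_legal(self, quick_config):
        cfg = dataclasses.replace(
            quick_config, prod=ProductivityModel(k0=1.0), env=EnvironmentConfig(t_mean=-20.0)
        )
        st = init_state(cfg)
        assert st.capacity == 0
        assert st.total_abundance == 0


class TestStepDynamics:
    def test_single_species_settles_near_interior_equilibrium(self, rng):
        # one well-matched species at its thermal optimum: abundance should
        # rise from a small founding population and fluctuate around a
        # stable interior level below the cap
        cfg = SimulationConfig(
            env=EnvironmentConfig(t_mean=30.0, sigma_short=0.0),
            n_steps=0,
            seed=1,
        )
        tpc = make_tpc(20.0, 40.0)  # peak at 30
        st = _state_with(cfg, [(tpc, 50)])
        demo = np.random.default_rng(10)
        arr = np.random.default_rng(11)
        traj = []
        for _ in range(3000):
            step(st, 30.0, cfg, demo, arr, arrive=False)
            traj.append(st.total_abundance)
        tail = np.array(traj[1500:])
        assert tail.min() > 0
        assert tail.mean() > 500  # grew far above founding size
        assert tail.max() <= st.capacity
        # stationarity: first and second half of the tail agree
        assert abs(tail[:750].mean() - tail[750:].mean()) / tail.mean() < 0.1

    def test_nonviable_species_dies_at_outside_rate(self, quick_config):
        # ctmax below every realized temperature: a pure death process at
        # the (scarcity-scaled) outside-range rate
        cfg = dataclasses.replace(
            quick_config, env=EnvironmentConfig(t_mean=18.0, sigma_short=0.0), n_steps=0
        )
        tpc = make_tpc(-20.0, -10.0)
        lifetimes = []
        for s in range(200):
            st = _state_with(cfg, [(tpc, 30)])
            demo = np.random.default_rng(s)
            arr = np.random.default_rng(1000 + s)
            t = 0
            while st.richness and t < 500:
                step(st, 18.0, cfg, demo, arr, arrive=False)
                t += 1
            lifetimes.append(t)
        # survival 1 - d_eff per step; cohort of 30 lasts ~ log(30)/d_eff
        from thermassembly.environment import productivity_multiplier

        pm = productivity_multiplier(cfg.prod, 18.0)
        d_eff = min(0.95, cfg.d_out / pm)
        expected = np.log(30) / d_eff
        assert np.mean(lifetimes) == pytest.approx(expected, rel=0.35)

    def test_identical_twins_stay_symmetric(self, quick_config):
        cfg = dataclasses.replace(quick_config, n_steps=0)
        tpc = make_tpc(10.0, 26.0)
        finals = []
        for s in range(300):
            st = _state_with(cfg, [(tpc, 100), (make_tpc(10.0, 26.0), 100)])
            demo = np.random.default_rng(s)
            arr = np.random.default_rng(5000 + s)
            for _ in range(100):
                step(st, 18.0, cfg, demo, arr, arrive=False)
            n = dict(zip(st.ids, st.abundance))
            finals.append((n.get(0, 0), n.get(1, 0)))
        finals = np.array(finals, dtype=float)
        # exchangeable species: equal means within Monte-Carlo error
        diff = finals[:, 0].mean() - finals[:, 1].mean()
        pooled_se = finals.std() / np.sqrt(len(finals))
        assert abs(diff) < 4 * pooled_se

    def test_cap_and_nonnegativity_invariants(self, quick_config):
        cfg = dataclasses.replace(quick_config, immigration_rate=0.2, n_steps=0)
        st = init_state(cfg)
        demo = np.random.default_rng(3)
        arr = np.random.default_rng(4)
        temps = np.random.default_rng(5).normal(18.0, 2.5, 400)
        for t in temps:
            step(st, t, cfg, demo, arr)
            assert st.total_abundance <= st.capacity
            assert np.all(st.abundance >= 0)


class TestRunSimulation:
    def test_zero_steps_returns_initial_assemblage(self, quick_config):
        cfg = dataclasses.replace(quick_config, n_steps=0)
        rec = run_simulation(cfg)
        assert rec.final_richness == cfg.n_init
        assert (rec.trait_table["n"] == cfg.n0).all()

    def test_no_immigration_nonviable_founders_go_extinct(self, quick_config):
        prior = TraitPrior(ctmin_low=60.0, ctmin_high=70.0)  # nothing survives 18 degC
        cfg = dataclasses.replace(quick_config, prior=prior, immigration_rate=0.0, n_steps=300)
        rec = run_simulation(cfg)
        assert rec.final_richness == 0
        assert rec.lifespans.size == cfg.n_init
        assert (rec.lifespans < 300).all()

    def test_bit_identical_given_seed(self, quick_config):
        a = run_simulation(quick_config)
        b = run_simulation(quick_config)
        pd.testing.assert_frame_equal(a.trait_table, b.trait_table)
        assert np.array_equal(a.lifespans, b.lifespans)
        pd.testing.assert_frame_equal(a.richness_trajectory, b.richness_trajectory)

    def test_default_regime_sustains_species(self):
        # benign mid-gradient conditions: the large majority of runs end
        # with a living assemblage
        alive = 0
        for s in range(20):
            cfg = SimulationConfig(
                env=EnvironmentConfig(t_mean=18.0, sigma_short=2.5, sigma_long=0.0),
                n_steps=4000,
                seed=s,
            )
            alive += run_simulation(cfg).final_richness > 0
        assert alive >= 16

    def test_lifespan_bookkeeping(self, quick_config):
        rec = run_simulation(quick_config)
        n_extinct = quick_config.n_init + 0  # founders may die; arrivals too
        assert rec.lifespans.size >= rec.final_richness
        assert (rec.lifespans >= 0).all()
        assert (rec.lifespans <= quick_config.n_steps).all()


class TestCountSchemeAgainstIndividualOracle:
    """The binomial/Poisson/multinomial species-count updates must match a
    naive per-individual Bernoulli simulation in distribution."""

    @staticmethod
    def _individual_sim(seed, n_steps=200):
        """Two species, per-individual fates, same rates as the count scheme."""
        rng = np.random.default_rng(seed)
        cfg = SimulationConfig(
            env=EnvironmentConfig(t_mean=18.0, sigma_short=0.0), seed=0, n_steps=0
        )
        tpcs = [make_tpc(8.0, 28.0), make_tpc(12.0, 24.0)]
        K = carrying_capacity(cfg.prod, cfg.env)
        from thermassembly.environment import productivity_multiplier

        pm = productivity_multiplier(cfg.prod, 18.0)
        scarcity = 1.0 / max(pm, 0.05)
        N = [120, 120]
        T = 18.0
        for _ in range(n_steps):
            perf = np.array([t.performance(T) for t in tpcs])
            q = perf / (perf + cfg.perf_half)
            d = np.minimum(scarcity * (cfg.d_out - (cfg.d_out - cfg.d_in) * q), 0.95)
            # per-individual deaths
            for i in (0, 1):
                N[i] -= int((rng.random(N[i]) < d[i]).sum())
            # per-individual offspring, same niche-crowding factor as the
            # count scheme (two identical-range species overlap fully)
            ntot = N[0] + N[1]
            lo = np.maximum.outer([t.ctmin for t in tpcs], [t.ctmin for t in tpcs])
            hi = np.minimum.outer([t.ctmax for t in tpcs], [t.ctmax for t in tpcs])
            width = np.array([t.width for t in tpcs])
            alpha_range = np.clip(hi - lo, 0, None) / width[:, None]
            # count-scheme alpha uses shape overlap; recompute exactly
            from thermassembly.simulator import AssemblageState, _empty_state

            st = _empty_state(K)
            st.add_species(tpcs[0], max(N[0], 1))
            st.add_species(tpcs[1], max(N[1], 1))
            alpha = st.competition_matrix()
            crowd = np.clip(1.0 - (alpha @ np.array(N)) / K, 0.0, None)
            free = K - ntot
            births = np.zeros(2, dtype=int)
            for i in (0, 1):
                lam = cfg.prod.r_max * pm * crowd[i] * perf[i]
                births[i] = rng.poisson(lam * N[i])
            total = births.sum()
            if total > 0 and free > 0:
                if total > free:
                    # uniform thinning of the birth pool to the free slots
                    keep = rng.choice(total, size=free, replace=False)
                    births = np.bincount(
                        (keep >= births[0]).astype(int), minlength=2
                    )
                N[0] += int(births[0])
                N[1] += int(births[1])
        return N

    @staticmethod
    def _count_sim(seed, n_steps=200):
        cfg = SimulationConfig(
            env=EnvironmentConfig(t_mean=18.0, sigma_short=0.0),
            immigration_rate=0.0,
            n_steps=0,
            seed=0,
        )
        st = _state_with(cfg, [(make_tpc(8.0, 28.0), 120), (make_tpc(12.0, 24.0), 120)])
        demo = np.random.default_rng(seed)
        arr = np.random.default_rng(99_000 + seed)
        for _ in range(n_steps):
            step(st, 18.0, cfg, demo, arr, arrive=False)
        n = dict(zip(st.ids, st.abundance))
        return [n.get(0, 0), n.get(1, 0)]

    def test_final_abundance_moments_match(self):
        n_seeds = 500
        ind = np.array([self._individual_sim(s) for s in range(n_seeds)], dtype=float)
        cnt = np.array([self._count_sim(s) for s in range(n_seeds)], dtype=float)
        ind_tot, cnt_tot = ind.sum(axis=1), cnt.sum(axis=1)
        assert cnt_tot.mean() == pytest.approx(ind_tot.mean(), rel=0.1)
        assert cnt_tot.std() == pytest.approx(ind_tot.std(), rel=0.35)
        # per-species means agree too
        for j in (0, 1):
            assert cnt[:, j].mean() == pytest.approx(ind[:, j].mean(), rel=0.15)


class TestCompetitionNarrowing:
    def test_competition_narrows_survivor_trait_spread(self):
        """With the performance-weighted lottery on, the surviving trait
        distribution is narrower than with neutral allocation."""
        sds_on, sds_off = [], []
        for s in range(12):
            base = SimulationConfig(
                env=EnvironmentConfig(t_mean=18.0, sigma_short=2.5),
                n_steps=4000,
                immigration_rate=0.05,
                seed=s,
            )
            for flag, sink in ((True, sds_on), (False, sds_off)):
                cfg = dataclasses.replace(base, competition=flag)
                tab = run_simulation(cfg).trait_table
                if len(tab) >= 2:
                    mid = (tab.ctmin_c + tab.ctmax_c) / 2
                    sink.append(float(mid.std()))
        assert np.mean(sds_on) <= np.mean(sds_off) * 1.05
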