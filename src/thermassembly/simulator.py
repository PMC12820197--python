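"""Eco-evolutionary assemblage dynamics.

Species are collections of exchangeable individuals sharing one thermal
performance curve (TPC).  Each time step, at the realized temperature
``T_t``:

1. *Mortality* (environmental filtering): every individual of species
   *i* dies with a probability that falls smoothly from ``d_out`` (no
   performance at ``T_t``) toward ``d_in`` (high performance), and all
   mortality is scaled by resource scarcity — the inverse of the
   ambient productivity multiplier — so benign productive environments
   relax the filter and harsh ones sharpen it.
2. *Arrival*: with probability ``immigration_rate`` one new species
   enters — drawn from the trait prior (immigration mode) or mutated
   from a resident parent chosen proportionally to abundance (mutation
   mode, sympatric speciation) — at ``min(n0, K - N_total)``
   individuals, claiming mortality-freed capacity before the lottery
   so the immigrant supply does not covary with favorability.
3. *Reproduction*: expected fecundity per species is
   ``f_i = r_max * productivity(T_t) * crowding_i * P_i(T_t) * N_i``,
   where ``crowding_i = max(0, 1 - (alpha N)_i / K)`` uses MacArthur
   competition coefficients from the overlap of normalized performance
   curves: thermally similar species compete strongly, dissimilar ones
   partition the resource axis.  Total recruit demand is
   Poisson(sum f_i), truncated to the free capacity ``K - N_total``.
4. *Lottery competition*: recruits are allocated multinomially with
   weights proportional to the expected fecundities — performance x
   abundance, damped by niche-local crowding.  With competition off,
   performance is removed from the allocation weights while the
   capacity cap and crowding are kept, isolating the abiotic filter.
5. Species at abundance 0 are marked extinct and their lifespan
   recorded.

Counts are species-level (binomial/Poisson/multinomial draws), which is
distributionally equivalent to simulating exchangeable individuals one
by one but runs orders of magnitude faster.

One master seed spawns independent child streams for the environment,
the demography, and the arrivals, so toggling a scenario switch does
not shift unrelated random draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .environment import (
    EnvironmentConfig,
    ProductivityModel,
    TemperatureSeries,
    carrying_capacity,
    productivity_multiplier,
    sample_temperature_series,
)
from .thermal_traits import (
    ThermalPerformanceCurve,
    TraitPrior,
    draw_immigrant,
    make_tpc,
    mutate_species,
)

__all__ = [
    "SimulationConfig",
    "AssemblageState",
    "SimulationRecord",
    "init_state",
    "step",
    "run_simulation",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Full parameterization of one simulation run."""

    env: EnvironmentConfig = field(default_factory=EnvironmentConfig)
    prod: ProductivityModel = field(default_factory=ProductivityModel)
    prior: TraitPrior = field(default_factory=TraitPrior)
    n_steps: int = 100_000
    d_in: float = 0.05
    d_out: float = 0.3
    immigration_rate: float = 0.02
    n0: int = 10
    n_init: int = 20
    speciation_mode: str = "immigration"
    competition: bool = True
    productivity_link: bool = True
    sigma_mut_ctmin: float = 1.0
    sigma_mut_width: float = 1.0
    perf_half: float = 0.5
    seed: int | np.random.SeedSequence = 0
    richness_thin: int = 100

    def __post_init__(self) -> None:
        if not (0.0 <= self.d_in <= self.d_out <= 1.0):
            raise ValueError("require 0 <= d_in <= d_out <= 1")
        if not (0.0 <= self.immigration_rate <= 1.0):
            raise ValueError("immigration_rate must be in [0, 1]")
        if self.n0 < 1:
            raise ValueError("n0 must be >= 1")
        if self.n_steps < 0:
            raise ValueError("n_steps must be >= 0")
        if self.n_init < 0:
            raise ValueError("n_init must be >= 0")
        if self.speciation_mode not in ("immigration", "mutation"):
            raise ValueError(f"unknown speciation_mode {self.speciation_mode!r}")


@dataclass
class _SpeciesRecord:
    species_id: int
    ctmin: float
    ctmax: float
    height: float
    birth_step: int
    death_step: Optional[int] = None  # None while extant


@dataclass
class AssemblageState:
    """Extant species (parallel arrays) plus lifespan bookkeeping.

    ``ctmin``/``ctmax``/``height``/``abundance``/``birth``/``ids`` are
    aligned arrays over currently extant species; ``closed`` holds
    records of extinct species.
    """

    ctmin: np.ndarray
    ctmax: np.ndarray
    height: np.ndarray
    abundance: np.ndarray
    birth: np.ndarray
    ids: np.ndarray
    capacity: int
    step_index: int = 0
    next_id: int = 0
    closed: list = field(default_factory=list)
    _alpha: np.ndarray = field(default=None, repr=False)
    _alpha_key: tuple = field(default=None, repr=False)

    @property
    def richness(self) -> int:
        return int(self.ctmin.size)

    def competition_matrix(self) -> np.ndarray:
        """MacArthur competition coefficients alpha_ij.

        alpha_ij = integral(p_i p_j) / integral(p_i p_i) with p the
        species' unit-area performance shape, so alpha_ii = 1 and a wide
        generalist exerts little crowding on a narrow specialist nested
        inside its range.  Cached until the species set changes.
        """
        key = (self.ctmin.size, self.ids[-1] if self.ids.size else -1)
        if self._alpha_key == key:
            return self._alpha
        s_ = self.ctmin.size
        if s_ == 0:
            alpha = np.empty((0, 0))
        else:
            # unit-area parabola on [ctmin, ctmax]: p(T) = 6 u (1-u) / w
            ng = 33
            grid = np.linspace(0.0, 1.0, ng)
            w = self.ctmax - self.ctmin
            T = self.ctmin[:, None] + w[:, None] * grid[None, :]  # (s, ng)
            # evaluate p_j at species i's support points
            u_ij = (T[:, None, :] - self.ctmin[None, :, None]) / w[None, :, None]
            p_ij = np.where(
                (u_ij > 0) & (u_ij < 1), 6.0 * u_ij * (1.0 - u_ij), 0.0
            ) / w[None, :, None]
            p_ii = (6.0 * grid * (1.0 - grid))[None, :] / w[:, None]
            # trapezoid over species i's own support
            wt = np.full(ng, 1.0)
            wt[0] = wt[-1] = 0.5
            dx = w / (ng - 1)
            num = (p_ii[:, None, :] * p_ij * wt[None, None, :]).sum(axis=2) * dx[:, None]
            den = (p_ii**2 * wt[None, :]).sum(axis=1) * dx
            alpha = num / den[:, None]
        self._alpha = alpha
        self._alpha_key = key
        return alpha

    @property
    def total_abundance(self) -> int:
        return int(self.abundance.sum())

    def add_species(self, tpc: ThermalPerformanceCurve, n: int) -> None:
        self.ctmin = np.append(self.ctmin, tpc.ctmin)
        self.ctmax = np.append(self.ctmax, tpc.ctmax)
        self.height = np.append(self.height, tpc.height)
        self.abundance = np.append(self.abundance, np.int64(n))
        self.birth = np.append(self.birth, np.int64(self.step_index))
        self.ids = np.append(self.ids, np.int64(self.next_id))
        self.next_id += 1

    def drop_extinct(self) -> None:
        dead = self.abundance == 0
        if not dead.any():
            return
        for i in np.flatnonzero(dead):
            self.closed.append(
                _SpeciesRecord(
                    species_id=int(self.ids[i]),
                    ctmin=float(self.ctmin[i]),
                    ctmax=float(self.ctmax[i]),
                    height=float(self.height[i]),
                    birth_step=int(self.birth[i]),
                    death_step=self.step_index,
                )
            )
        keep = ~dead
        self.ctmin = self.ctmin[keep]
        self.ctmax = self.ctmax[keep]
        self.height = self.height[keep]
        self.abundance = self.abundance[keep]
        self.birth = self.birth[keep]
        self.ids = self.ids[keep]


@dataclass(frozen=True)
class SimulationRecord:
    """Outcome of a run: final trait table, richness trajectory, lifespans."""

    trait_table: pd.DataFrame
    richness_trajectory: pd.DataFrame
    lifespans: np.ndarray
    n_steps: int
    capacity: int
    config: SimulationConfig
    series: Optional[TemperatureSeries] = None

    @property
    def final_richness(self) -> int:
        return int(len(self.trait_table))

    @property
    def mean_lifespan(self) -> float:
        return float(self.lifespans.mean()) if self.lifespans.size else float("nan")


def _empty_state(capacity: int) -> AssemblageState:
    z = np.empty(0)
    return AssemblageState(
        ctmin=z.copy(),
        ctmax=z.copy(),
        height=z.copy(),
        abundance=np.empty(0, dtype=np.int64),
        birth=np.empty(0, dtype=np.int64),
        ids=np.empty(0, dtype=np.int64),
        capacity=capacity,
    )


def init_state(
    cfg: SimulationConfig,
    rng_arrivals: Optional[np.random.Generator] = None,
) -> AssemblageState:
    """Found the assemblage with ``n_init`` prior draws at abundance n0 each.

    A zero carrying capacity is legal (no arrival can ever establish);
    founders are truncated to the free capacity like any arrival.
    """
    if rng_arrivals is None:
        ss = np.random.SeedSequence(cfg.seed) if not isinstance(
            cfg.seed, np.random.SeedSequence
        ) else cfg.seed
        rng_arrivals = np.random.default_rng(ss.spawn(3)[2])
    K = carrying_capacity(cfg.prod, cfg.env, cfg.productivity_link)
    state = _empty_state(K)
    for _ in range(cfg.n_init):
        free = K - state.total_abundance
        if free <= 0:
            break
        tpc = draw_immigrant(cfg.prior, rng_arrivals)
        state.add_species(tpc, min(cfg.n0, free))
    return state


def step(
    state: AssemblageState,
    temperature: float,
    cfg: SimulationConfig,
    rng_demography: np.random.Generator,
    rng_arrivals: np.random.Generator,
    arrive: Optional[bool] = None,
) -> AssemblageState:
    """Advance the assemblage one time step (mutates and returns ``state``).

    ``arrive`` forces or suppresses the arrival event; by default it is
    drawn Bernoulli(immigration_rate) from the arrivals stream.
    """
    K = state.capacity
    pm = productivity_multiplier(cfg.prod, float(temperature), cfg.productivity_link)

    def _performance() -> np.ndarray:
        u = (temperature - state.ctmin) / (state.ctmax - state.ctmin)
        return np.where((u > 0.0) & (u < 1.0), 6.0 * state.height * u * (1.0 - u), 0.0)

    N = state.abundance
    perf = _performance()
    # resource scarcity elevates mortality: per-step death rates are the
    # baseline rates divided by the ambient productivity multiplier, so
    # benign productive environments relax the environmental filter
    pm_mean = productivity_multiplier(cfg.prod, cfg.env.t_mean, cfg.productivity_link)
    scarcity = 1.0 / max(pm_mean, 0.05)
    if N.size:
        # 1. mortality declines smoothly from d_out (no performance) toward
        # d_in (high performance); the filter is sharpest where resources
        # are scarce and relaxes in productive environments
        q = perf / (perf + cfg.perf_half)
        d = np.minimum(scarcity * (cfg.d_out - (cfg.d_out - cfg.d_in) * q), 0.95)
        N -= rng_demography.binomial(N, d)
    # 2. arrival claims mortality-freed capacity before the lottery;
    # otherwise saturated (favorable) environments would never admit
    # immigrants and the immigrant supply would covary with favorability
    if arrive is None:
        arrive = rng_arrivals.random() < cfg.immigration_rate
    if arrive:
        free = K - state.total_abundance
        if free > 0:
            if cfg.speciation_mode == "mutation" and state.total_abundance > 0:
                probs = state.abundance / state.total_abundance
                parent_idx = rng_arrivals.choice(state.richness, p=probs)
                parent = make_tpc(
                    float(state.ctmin[parent_idx]),
                    float(state.ctmax[parent_idx]),
                    mode="relaxed",
                    a0_or_height=float(state.height[parent_idx]),
                )
                mode = "relaxed" if cfg.prior.relaxed_mode else "constrained"
                parent = replace(parent, mode=mode)
                tpc = mutate_species(
                    parent, cfg.sigma_mut_ctmin, cfg.sigma_mut_width, rng_arrivals
                )
            else:
                tpc = draw_immigrant(cfg.prior, rng_arrivals)
            state.add_species(tpc, min(cfg.n0, free))
            N = state.abundance
            perf = _performance()
    if N.size:
        # 3. reproduction demand: productivity scales fecundity; crowding is
        # niche-local, with MacArthur competition coefficients from the
        # overlap of normalized performance curves, so dissimilar thermal
        # strategies partition the resource axis and coexist stably
        n_total = int(N.sum())
        free = K - n_total
        if K > 0:
            alpha = state.competition_matrix()
            crowding = np.clip(1.0 - (alpha @ N) / K, 0.0, None)
        else:
            crowding = 0.0
        fec = cfg.prod.r_max * pm * crowding * perf * N
        demand = float(fec.sum())
        if demand > 0.0 and free > 0:
            recruits = min(int(rng_demography.poisson(demand)), free)
            if recruits > 0:
                # 4. lottery allocation: weights are the species' expected
                # fecundities (performance x abundance, damped by niche-local
                # crowding); without competition, performance is removed
                w = fec if cfg.competition else N * crowding
                ws = w.sum()
                if ws > 0.0:
                    N += rng_demography.multinomial(recruits, w / ws)
    # 5. extinctions
    state.drop_extinct()
    state.step_index += 1
    return state


def run_simulation(cfg: SimulationConfig, keep_series: bool = False) -> SimulationRecord:
    """Run the full eco-evolutionary simulation; identical seed, identical record."""
    ss = cfg.seed if isinstance(cfg.seed, np.random.SeedSequence) else np.random.SeedSequence(cfg.seed)
    env_ss, demo_ss, arr_ss = ss.spawn(3)
    rng_demo = np.random.default_rng(demo_ss)
    rng_arr = np.random.default_rng(arr_ss)

    state = init_state(cfg, rng_arrivals=rng_arr)
    K = state.capacity

    rich_steps: list[int] = [0]
    rich_vals: list[int] = [state.richness]

    if cfg.n_steps > 0:
        series = sample_temperature_series(cfg.env, cfg.n_steps, env_ss)
        temps = series.values
        # pre-draw arrival events so scenario toggles do not shift them
        arrivals = rng_arr.random(cfg.n_steps) < cfg.immigration_rate
        thin = max(1, cfg.richness_thin)
        for t in range(cfg.n_steps):
            step(state, temps[t], cfg, rng_demo, rng_arr, arrive=bool(arrivals[t]))
            if (t + 1) % thin == 0 or t + 1 == cfg.n_steps:
                rich_steps.append(t + 1)
                rich_vals.append(state.richness)
    else:
        series = None

    table = pd.DataFrame(
        {
            "species": [f"sp{int(i):06d}" for i in state.ids],
            "ctmin_c": state.ctmin,
            "ctmax_c": state.ctmax,
            "n": state.abundance,
            "site": "sim",
        }
    )
    lifespans = np.array(
        [r.death_step - r.birth_step for r in state.closed]
        + [cfg.n_steps - int(b) for b in state.birth],
        dtype=float,
    )
    traj = pd.DataFrame({"step": rich_steps, "richness": rich_vals})
    return SimulationRecord(
        trait_table=table,
        richness_trajectory=traj,
        lifespans=lifespans,
        n_steps=cfg.n_steps,
        capacity=K,
        config=cfg,
        series=series if keep_series else None,
    )
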