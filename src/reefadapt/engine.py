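"""Simulation engine: staged burn-in, per-generation Wright-Fisher update with
migration, fitness-dependent demography, and the warming period.

Life cycle of one generation, per destination population:

1. phenotypes and Gaussian fitness are computed against the realized
   temperature of the current generation;
2. when fitness-dependent demography is active, the next generation's census
   is the carrying capacity scaled by mean fitness relative to its historical
   (pre-warming) level, and emigration scales identically;
3. each offspring of the next generation is an immigrant from source *i* with
   probability rates[i][j] * emigration_scale_i, otherwise a resident (any
   shortfall in immigrant supply is reassigned to residents: a destination's
   size is set by its own fitness, not by immigrant availability);
4. the offspring's two parents are drawn fitness-proportionally within its
   parental population, and its haplotypes are two freely recombining,
   possibly mutated gametes.

The burn-in runs a staged plan: early stages use proportionally smaller
populations with proportionally higher mutation rates (N·mu preserved), which
equilibrates standing genetic variation orders of magnitude faster; stage
transitions resize through the next Wright-Fisher draw.  All randomness flows
from a single seeded generator; runs are bit-reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import genetics, observables, selection
from .config import ScenarioConfig
from .environment import EnvSeries, generate_env
from .genetics import HaplotypeState
from .selection import DemographicState, EXTINCTION_FLOOR

__all__ = ["MetapopState", "StagePlan", "RunResult", "step_generation", "run_burnin", "run_scenario"]

logger = logging.getLogger("reefadapt")

#: generations of mean fitness averaged into the historical reference
HISTORICAL_WINDOW = 100

#: heartbeat interval for progress logging
_LOG_EVERY = 1000


@dataclass
class StagePlan:
    """Ordered burn-in stages of (size divisor, mutation multiplier, generations)."""

    stages: tuple[tuple[float, float, int], ...]

    @classmethod
    def from_config(cls, cfg: ScenarioConfig) -> "StagePlan":
        return cls(tuple((s.size_divisor, s.mut_multiplier, s.n_generations) for s in cfg.environment.burnin_stages))

    @property
    def total_generations(self) -> int:
        return sum(g for _, _, g in self.stages)

    def at(self, generation: int) -> tuple[float, float]:
        """(size_divisor, mut_multiplier) in force at a burn-in generation;
        past the burn-in, the final stage's values apply."""
        t = generation
        for div, mult, g in self.stages:
            if t < g:
                return div, mult
            t -= g
        return self.stages[-1][0], self.stages[-1][1]


@dataclass
class MetapopState:
    """Mutable state of the whole metapopulation during a run."""

    states: list[HaplotypeState | None]
    demo: DemographicState
    generation: int
    rng: np.random.Generator

    @property
    def n_extant(self) -> int:
        return int(np.sum(self.demo.current_size > 0))


@dataclass
class RunResult:
    """Everything a finished run produced."""

    config: ScenarioConfig
    trace: "observables.PopTrace"
    meta: "observables.MetaTrace"
    env: EnvSeries
    warming_onset: int
    extinction_generation: dict[str, int | None]
    metapop_extinction: int | None
    final_state: MetapopState | None = None

    @property
    def warming_generations_survived(self) -> int:
        """Generations into the warming period before metapopulation extinction
        (censored at the configured warming length if the run survived)."""
        horizon = self.config.environment.warming_generations
        if self.metapop_extinction is None:
            return horizon
        return int(np.clip(self.metapop_extinction - self.warming_onset, 0, horizon))


def _target_sizes(cfg: ScenarioConfig, divisor: float) -> np.ndarray:
    return np.maximum(EXTINCTION_FLOOR, np.round(cfg.census_sizes / divisor)).astype(int)


def step_generation(
    state: MetapopState,
    fitness_by_pop: list[np.ndarray | None],
    next_sizes: np.ndarray,
    rates: np.ndarray,
    mut_rate: float,
    effect_sd: float,
) -> None:
    """Produce the next generation in place.

    ``fitness_by_pop`` holds the current generation's per-individual fitness;
    ``next_sizes`` the census of the generation being created.  A population
    whose size is 0, or whose residents all have zero fitness, produces
    nothing and is extinct.
    """
    rng = state.rng
    k = len(state.states)
    emig = state.demo.emigration_scale
    totals = np.array(
        [w.sum() if w is not None else 0.0 for w in fitness_by_pop]
    )
    new_states: list[HaplotypeState | None] = [None] * k
    realized_sizes = np.zeros(k, dtype=int)

    for j in range(k):
        n_j = int(next_sizes[j])
        if n_j <= 0 or state.states[j] is None:
            continue
        if totals[j] <= 0:  # residents cannot reproduce
            continue
        # immigrant sourcing probabilities (viable sources only)
        src, p = [], []
        for i in range(k):
            if i == j:
                continue
            q = rates[i, j] * emig[i]
            if q > 0 and state.states[i] is not None and totals[i] > 0:
                src.append(i)
                p.append(q)
        p_res = 1.0 - sum(p)
        counts = rng.multinomial(n_j, [p_res] + p)
        parts = []
        for c, i_pop in zip(counts, [j] + src):
            if c == 0:
                continue
            parents = selection.choose_parents(fitness_by_pop[i_pop], int(c), rng)
            src_state = state.states[i_pop]
            gam0 = genetics.make_gametes(src_state, parents[:, 0], mut_rate, effect_sd, rng)
            gam1 = genetics.make_gametes(src_state, parents[:, 1], mut_rate, effect_sd, rng)
            parts.append(np.stack([gam0, gam1], axis=1))
        values = parts[0] if len(parts) == 1 else np.concatenate(parts, axis=0)
        new_states[j] = HaplotypeState(values)
        realized_sizes[j] = n_j

    state.states = new_states
    state.demo.current_size = realized_sizes
    state.demo.emigration_scale = np.where(realized_sizes > 0, state.demo.emigration_scale, 0.0)
    state.generation += 1


def _run(
    cfg: ScenarioConfig,
    n_generations: int,
    warming_onset: int,
    env: EnvSeries,
    collect_trace: bool = True,
    checkpoint_dir: str | Path | None = None,
) -> RunResult:
    cfg.validate()
    plan = StagePlan.from_config(cfg)
    genp = cfg.genetics
    rates = cfg.migration.rates
    names = cfg.names
    k = cfg.n_populations

    ss = np.random.SeedSequence(cfg.seed)
    rng = np.random.default_rng(ss.spawn(2)[1])

    div0, _ = plan.at(0)
    sizes0 = _target_sizes(cfg, div0)
    states: list[HaplotypeState | None] = [
        HaplotypeState.founders(int(n), genp.n_qtl) for n in sizes0
    ]
    demo = DemographicState(base_sizes=sizes0.copy(), current_size=sizes0.copy())
    state = MetapopState(states=states, demo=demo, generation=0, rng=rng)

    activation = warming_onset - cfg.environment.demography_lead
    hist_window: list[np.ndarray] = []
    hist_frozen = False
    collector = observables.TraceCollector(names) if collect_trace else None
    extinction_gen: dict[str, int | None] = {n: None for n in names}
    metapop_extinction: int | None = None
    prev_divisor = div0

    for t in range(n_generations):
        divisor, mult = plan.at(t)
        if divisor != prev_divisor:
            logger.info("generation %d: burn-in stage change, size divisor %g", t, divisor)
            if checkpoint_dir is not None:
                _checkpoint(state, names, t, checkpoint_dir)
            prev_divisor = divisor

        env_row = env.temps[t]
        # phenotypes and fitness of the current generation (fixed pop order)
        breeding_by_pop: list[np.ndarray | None] = [None] * k
        fitness_by_pop: list[np.ndarray | None] = [None] * k
        mean_fitness = np.full(k, np.nan)
        for p_idx in range(k):
            st = state.states[p_idx]
            if st is None:
                continue
            bv = genetics.breeding_values(st, genp.dominance)
            ph = genetics.phenotypes(bv, genp.esd, rng)
            w = selection.gaussian_fitness(ph.phenotype, float(env_row[p_idx]), genp.sigma)
            breeding_by_pop[p_idx] = bv
            fitness_by_pop[p_idx] = w
            mean_fitness[p_idx] = w.mean()

        if collector is not None:
            collector.add(t, breeding_by_pop, fitness_by_pop, state.demo.current_size, env_row)

        for p_idx, n in enumerate(names):
            if extinction_gen[n] is None and state.demo.current_size[p_idx] == 0:
                extinction_gen[n] = t
        if state.n_extant == 0:
            metapop_extinction = t
            logger.info("generation %d: metapopulation extinct", t)
            break

        if t % _LOG_EVERY == 0:
            logger.debug("generation %d / %d", t, n_generations)
        if t == n_generations - 1:
            break

        # demography scaling applies to every generation created at or after
        # the activation point (demography_lead generations before warming)
        if not hist_frozen:
            hist_window.append(mean_fitness)
            if len(hist_window) > HISTORICAL_WINDOW:
                hist_window.pop(0)
        active = (t + 1) >= activation
        state.demo.base_sizes = _target_sizes(cfg, plan.at(t + 1)[0])
        if active:
            if not hist_frozen:
                # reference = mean fitness over the generations preceding activation
                state.demo.historical_fitness = np.nanmean(np.stack(hist_window), axis=0)
                hist_frozen = True
                logger.info(
                    "generation %d: demography activated, historical fitness %s",
                    t,
                    state.demo.historical_fitness,
                )
            selection.scale_demography(mean_fitness, state.demo, active=True)
        else:
            selection.scale_demography(mean_fitness, state.demo, active=False)

        mut = min(1.0, genp.mut_rate * plan.at(t + 1)[1])
        step_generation(state, fitness_by_pop, state.demo.current_size, rates, mut, genp.effect_sd)

    if metapop_extinction is None and state.n_extant == 0:
        metapop_extinction = state.generation

    trace, meta = (
        collector.finalize() if collector is not None else (observables.PopTrace.empty(names), observables.MetaTrace.empty())
    )
    return RunResult(
        config=cfg,
        trace=trace,
        meta=meta,
        env=env,
        warming_onset=warming_onset,
        extinction_generation=extinction_gen,
        metapop_extinction=metapop_extinction,
        final_state=state,
    )


def _checkpoint(state: MetapopState, names: list[str], generation: int, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for n, st in zip(names, state.states):
        if st is not None:
            genetics.state_to_tsv(st, out / f"checkpoint_g{generation}_{n}.tsv")


def run_burnin(
    cfg: ScenarioConfig,
    plan: StagePlan | None = None,
    collect_trace: bool = True,
) -> RunResult:
    """Run only the pre-adaptation (burn-in) phase and return its result.

    The returned ``final_state`` carries the equilibrated genetic state and
    the recorded historical fitness reference.
    """
    if plan is not None:
        from .config import BurninStage
        import dataclasses

        env_params = dataclasses.replace(
            cfg.environment, burnin_stages=tuple(BurninStage(*s) for s in plan.stages)
        )
        cfg = dataclasses.replace(cfg, environment=env_params).validate()
    onset = cfg.environment.total_burnin
    ss = np.random.SeedSequence(cfg.seed)
    env = generate_env(cfg.environment, cfg.populations, onset, ss.spawn(2)[0], warming_onset=onset)
    return _run(cfg, onset, onset, env, collect_trace=collect_trace)


def run_scenario(
    cfg: ScenarioConfig,
    collect_trace: bool = True,
    checkpoint_dir: str | Path | None = None,
) -> RunResult:
    """Run a full scenario: burn-in, demography lead-in, warming period.

    Fully reproducible given ``cfg.seed``; the environment series is generated
    up front for the whole run (warming continues past extinction).
    """
    onset = cfg.environment.total_burnin
    n_gen = onset + cfg.environment.warming_generations
    ss = np.random.SeedSequence(cfg.seed)
    env = generate_env(cfg.environment, cfg.populations, n_gen, ss.spawn(2)[0], warming_onset=onset)
    return _run(cfg, n_gen, onset, env, collect_trace=collect_trace, checkpoint_dir=checkpoint_dir)
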