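"""Shared fixtures.

The expensive scenario ensembles (ten replicate warming runs of the reduced
GBR scenario, their migration-free counterparts, and the perfect-heritability
burn-in) are session-scoped and shared across test modules.

The reduced scenario divides census sizes by 10 and multiplies the mutation
rate by 10 (preserving N·mu, which sets equilibrium standing variation) and
shortens the staged burn-in to (100x, 1000) + (10x, 1000) + (1x, 2000)
generations — the smaller stage populations equilibrate proportionally
faster, so the shorter plan reaches the same mutation-drift-selection
balance.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

import reefadapt as ra

SCALED_STAGES = ((100, 100, 1000), (10, 10, 1000), (1, 1, 2000))
N_REPLICATES = 10


def scaled_gbr(seed: int, **genetic_overrides) -> ra.ScenarioConfig:
    """The 1/10-scale GBR reference scenario used throughout the suite."""
    cfg = ra.load_packaged("gbr")
    cfg = ra.rescale_scenario(
        cfg, 10, burnin_stages=SCALED_STAGES, demography_lead=500
    )
    if genetic_overrides:
        cfg = dataclasses.replace(
            cfg, genetics=dataclasses.replace(cfg.genetics, **genetic_overrides)
        )
    return cfg.replace(seed=seed)


def tiny_scenario(
    seed: int = 0,
    n_pops: int = 1,
    census: int = 200,
    offsets: tuple[float, ...] | None = None,
    migration: float = 0.0,
    **genetic_overrides,
) -> ra.ScenarioConfig:
    """A small, fast scenario for unit-level engine tests."""
    offsets = offsets or (0.0,) * n_pops
    pops = tuple(
        ra.PopulationSpec(name=f"P{i}", census_size=census, thermal_offset=offsets[i])
        for i in range(n_pops)
    )
    rates = np.full((n_pops, n_pops), migration)
    np.fill_diagonal(rates, 0.0)
    genetics = ra.GeneticParams(
        n_qtl=10, effect_sd=0.2, mut_rate=1e-4, esd=0.0, sigma=1.0, dominance=0.5
    )
    genetics = dataclasses.replace(genetics, **genetic_overrides)
    env = ra.EnvParams(
        anomaly_sd=0.0,
        warming_rate=0.0,
        burnin_stages=(ra.BurninStage(10, 10, 100), ra.BurninStage(1, 1, 200)),
        demography_lead=0,
        warming_generations=10,
    )
    return ra.ScenarioConfig(
        populations=pops,
        migration=ra.MigrationMatrix(rates),
        genetics=genetics,
        environment=env,
        seed=seed,
    ).validate()


@pytest.fixture(scope="session")
def warming_runs() -> list[ra.RunResult]:
    """Ten replicate warming runs of the reduced GBR scenario (Esd=1, sigma=1)."""
    return [ra.run_scenario(scaled_gbr(seed)) for seed in range(N_REPLICATES)]


@pytest.fixture(scope="session")
def nomig_runs() -> list[ra.RunResult]:
    """The same ten seeds with the migration matrix zeroed."""
    runs = []
    for seed in range(N_REPLICATES):
        cfg = scaled_gbr(seed)
        cfg = dataclasses.replace(
            cfg, migration=ra.MigrationMatrix(np.zeros((5, 5)))
        ).validate()
        runs.append(ra.run_scenario(cfg))
    return runs


@pytest.fixture(scope="session")
def mu_sweep_runs() -> dict[tuple[int, float], ra.RunResult]:
    """Warming runs at ten-fold lower / higher mutation rate, two seeds each."""
    return {
        (seed, mu): ra.run_scenario(scaled_gbr(seed, mut_rate=mu))
        for seed in (0, 1)
        for mu in (1e-6, 1e-4)
    }


@pytest.fixture(scope="session")
def narrow_burnin() -> ra.RunResult:
    """Burn-in under perfect heritability and narrow tolerance (Esd=0, sigma=0.5)."""
    return ra.run_burnin(scaled_gbr(3, esd=0.0, sigma=0.5))
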