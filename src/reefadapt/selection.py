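"""Gaussian thermal fitness, fitness-proportional parentage, and
fitness-dependent demography.

Fitness is an unnormalized Gaussian of the mismatch between an individual's
phenotype (its thermal optimum, °C) and the realized environmental
temperature:

    w = exp(-(phenotype - T_env)^2 / (2 sigma^2))

with peak 1 at zero mismatch; ``sigma`` is the breadth of the thermal
tolerance curve.  At 1 °C mismatch this gives fitness drops of ~86% at
sigma = 0.5 and ~39% at sigma = 1.

When fitness-dependent demography is active, a population whose mean fitness
falls relative to its historical (pre-warming) level shrinks linearly in size
and contributes proportionally fewer emigrants; below two individuals it is
extinct and never recolonizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ExtinctionSignal",
    "FitnessVector",
    "DemographicState",
    "gaussian_fitness",
    "fitness_drop_percent",
    "choose_parents",
    "scale_demography",
]

#: minimum viable census; biparental reproduction needs two individuals
EXTINCTION_FLOOR = 2


class ExtinctionSignal(RuntimeError):
    """Raised when no individual has positive fitness (population is dead)."""


@dataclass(frozen=True)
class FitnessVector:
    """Per-individual relative fitness in (0, 1]."""

    w: np.ndarray


@dataclass
class DemographicState:
    """Fitness-dependent demographic state of the metapopulation.

    base_sizes
        configured carrying capacities (per population).
    current_size
        realized census sizes; 0 marks an extinct population.
    historical_fitness
        per-population reference mean fitness (recorded at demography
        activation as the average over the preceding window); NaN until set.
    emigration_scale
        per-population multiplier in [0, 1] applied to outgoing migration.
    """

    base_sizes: np.ndarray
    current_size: np.ndarray = field(default=None)  # type: ignore[assignment]
    historical_fitness: np.ndarray = field(default=None)  # type: ignore[assignment]
    emigration_scale: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.base_sizes = np.asarray(self.base_sizes, dtype=int)
        if self.current_size is None:
            self.current_size = self.base_sizes.copy()
        self.current_size = np.asarray(self.current_size, dtype=int)
        if self.historical_fitness is None:
            self.historical_fitness = np.full(len(self.base_sizes), np.nan)
        if self.emigration_scale is None:
            self.emigration_scale = np.ones(len(self.base_sizes))

    @property
    def extant(self) -> np.ndarray:
        return self.current_size > 0


def gaussian_fitness(
    phenotype: np.ndarray | float, env_temp: float, sigma: float
) -> np.ndarray | float:
    """Relative fitness of phenotype(s) at environmental temperature ``env_temp``."""
    if not (sigma > 0):
        raise ValueError(f"sigma must be > 0, got {sigma}")
    mismatch = np.asarray(phenotype, dtype=float) - env_temp
    w = np.exp(-(mismatch**2) / (2.0 * sigma**2))
    return float(w) if np.isscalar(phenotype) else w


def fitness_drop_percent(mismatch: float, sigma: float) -> float:
    """Percent fitness lost at a given phenotype-environment mismatch."""
    return 100.0 * (1.0 - gaussian_fitness(mismatch, 0.0, sigma))


def choose_parents(
    fitness: np.ndarray | FitnessVector, n_offspring: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw (n_offspring, 2) parent index pairs, each slot independently with
    probability proportional to fitness.

    Selfing is permitted (hermaphroditic broadcast spawner).  Raises
    :class:`ExtinctionSignal` when total fitness is zero.
    """
    w = fitness.w if isinstance(fitness, FitnessVector) else np.asarray(fitness, dtype=float)
    total = w.sum()
    if not (total > 0):
        raise ExtinctionSignal("all individuals have zero fitness")
    cdf = np.cumsum(w)
    u = rng.random((int(n_offspring), 2)) * cdf[-1]
    return np.searchsorted(cdf, u, side="right").clip(0, len(w) - 1)


def scale_demography(
    mean_fitness: np.ndarray,
    state: DemographicState,
    active: bool = True,
) -> DemographicState:
    """Update census sizes and emigration scales from current mean fitness.

    When active, size_j = round(base_j * clamp(mean_fitness_j /
    historical_fitness_j, 0, 1)); the same clamped ratio scales emigration.
    Sizes never exceed the configured carrying capacity (populations cannot
    outgrow their habitat).  A census below two individuals is extinction:
    size 0, no emigration, permanent.  When inactive, sizes sit at base and
    scales at 1 (extinct populations stay extinct either way).
    """
    mean_fitness = np.asarray(mean_fitness, dtype=float)
    alive = state.extant
    if not active:
        state.current_size = np.where(alive, state.base_sizes, 0)
        state.emigration_scale = np.where(alive, 1.0, 0.0)
        return state
    if np.any(alive & ~np.isfinite(state.historical_fitness)):
        raise ValueError("historical_fitness must be recorded before demography activates")
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.clip(mean_fitness / state.historical_fitness, 0.0, 1.0)
    ratio = np.where(alive & np.isfinite(ratio), ratio, 0.0)
    new_size = np.round(state.base_sizes * ratio).astype(int)
    new_size[new_size < EXTINCTION_FLOOR] = 0
    new_size[~alive] = 0
    state.current_size = new_size
    state.emigration_scale = np.where(new_size > 0, ratio, 0.0)
    return state
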