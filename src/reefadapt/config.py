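"""Scenario configuration: types, validation, file I/O and demographic unit conversions.

A scenario bundles everything needed to run one simulated experiment:

* a list of populations (name, census size, thermal offset in °C relative to
  the mild-regime optimum),
* a pairwise per-generation migration matrix (``rates[i][j]`` = fraction of
  population *j*'s offspring whose parents are drawn from population *i*;
  source rows, destination columns),
* the genetic architecture (number of QTLs, mutation effect-size SD, per-locus
  per-gamete mutation rate, non-heritable noise SD ``esd``, tolerance breadth
  ``sigma``, dominance),
* the environmental regime (anomaly SD, warming rate and duration, staged
  burn-in plan, length of the fitness-dependent-demography lead-in),
* a seed.

Scenarios are stored as a single YAML document so that validation is atomic.
Unknown keys are rejected; every invariant is checked on load.

This module also implements the arithmetic for converting diffusion-scaled
demographic estimates (theta, T, M as reported by AFS model fitting) into
natural units (effective size in individuals, per-generation migrant fraction,
time in years).
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

__all__ = [
    "PopulationSpec",
    "MigrationMatrix",
    "GeneticParams",
    "BurninStage",
    "EnvParams",
    "ScenarioConfig",
    "DadiEstimate",
    "ScenarioFormatError",
    "ScenarioValidationError",
    "load_scenario",
    "save_scenario",
    "load_packaged",
    "packaged_scenario_path",
    "migration_to_tsv",
    "migration_from_tsv",
    "ne_from_theta",
    "m_from_scaled",
    "years_from_scaled_time",
    "matched_effect_sd",
    "rescale_scenario",
    "random_scenario",
]

#: default generation time (years); corals reach full reproductive output slowly
DEFAULT_GEN_TIME = 5.0

#: default mutation rate per genotyped (2bRAD) genome fraction per generation
DEFAULT_MU_FRAC = 0.018


class ScenarioFormatError(ValueError):
    """The scenario file could not be parsed as structured text."""


class ScenarioValidationError(ValueError):
    """A parsed scenario violates an invariant.

    ``field`` names the offending entry.
    """

    def __init__(self, field_name: str, message: str):
        self.field = field_name
        super().__init__(f"{field_name}: {message}")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PopulationSpec:
    """One population: label, carrying-capacity census size, thermal offset (°C)."""

    name: str
    census_size: int
    thermal_offset: float

    def validate(self) -> None:
        if not self.name:
            raise ScenarioValidationError("populations.name", "must be non-empty")
        if int(self.census_size) != self.census_size or self.census_size < 2:
            raise ScenarioValidationError(
                f"populations[{self.name}].census_size",
                f"must be an integer >= 2, got {self.census_size}",
            )
        if not math.isfinite(self.thermal_offset):
            raise ScenarioValidationError(
                f"populations[{self.name}].thermal_offset", "must be finite"
            )


@dataclass(frozen=True)
class MigrationMatrix:
    """Square per-generation immigration-fraction matrix.

    ``rates[i][j]`` is the fraction of destination population *j*'s offspring
    whose parents are drawn from source population *i* (source rows,
    destination columns).  Diagonal entries are zero; residency is the
    complement of each destination column's sum.
    """

    rates: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "rates", np.asarray(self.rates, dtype=float))

    @property
    def n(self) -> int:
        return self.rates.shape[0]

    def validate(self) -> None:
        r = self.rates
        if r.ndim != 2 or r.shape[0] != r.shape[1]:
            raise ScenarioValidationError("migration.rates", "must be a square matrix")
        if not np.all(np.isfinite(r)):
            raise ScenarioValidationError("migration.rates", "entries must be finite")
        if np.any(r < 0):
            raise ScenarioValidationError("migration.rates", "entries must be >= 0")
        if np.any(np.diag(r) != 0):
            raise ScenarioValidationError(
                "migration.rates", "diagonal must be 0 (residency is the complement)"
            )
        colsum = r.sum(axis=0)
        if np.any(colsum >= 1):
            j = int(np.argmax(colsum))
            raise ScenarioValidationError(
                "migration.rates",
                f"immigration into destination column {j} sums to {colsum[j]:.4g} >= 1",
            )

    def __eq__(self, other) -> bool:  # dataclass eq breaks on ndarray fields
        return isinstance(other, MigrationMatrix) and np.array_equal(self.rates, other.rates)


@dataclass(frozen=True)
class GeneticParams:
    """Genetic architecture and phenotype parameters.

    n_qtl
        number of unlinked quantitative trait loci controlling thermal optimum.
    effect_sd
        SD (°C) of the normal distribution of new-mutation effect sizes.
    mut_rate
        per-locus per-gamete mutation probability.
    esd
        SD (°C) of the non-heritable noise added to the breeding value;
        0 means heritability 1.
    sigma
        breadth of the Gaussian thermal-tolerance curve (°C).
    dominance
        per-locus dominance coefficient h in [0, 1]; 0.5 is purely additive.
    """

    n_qtl: int = 10
    effect_sd: float = 0.2
    mut_rate: float = 1e-6
    esd: float = 1.0
    sigma: float = 1.0
    dominance: float = 0.5

    def validate(self) -> None:
        if int(self.n_qtl) != self.n_qtl or self.n_qtl < 1:
            raise ScenarioValidationError("genetics.n_qtl", "must be an integer >= 1")
        if not (self.effect_sd > 0):
            raise ScenarioValidationError("genetics.effect_sd", "must be > 0")
        if not (0 <= self.mut_rate <= 1):
            raise ScenarioValidationError("genetics.mut_rate", "must be in [0, 1]")
        if not (self.esd >= 0):
            raise ScenarioValidationError("genetics.esd", "must be >= 0")
        if not (self.sigma > 0):
            raise ScenarioValidationError("genetics.sigma", "must be > 0")
        if not (0 <= self.dominance <= 1):
            raise ScenarioValidationError("genetics.dominance", "must be in [0, 1]")


@dataclass(frozen=True)
class BurninStage:
    """One burn-in stage: run ``n_generations`` at census/size_divisor with
    mutation rate multiplied by ``mut_multiplier``."""

    size_divisor: float
    mut_multiplier: float
    n_generations: int

    def validate(self, idx: int) -> None:
        f = f"environment.burnin_stages[{idx}]"
        if not (self.size_divisor >= 1):
            raise ScenarioValidationError(f + ".size_divisor", "must be >= 1")
        if not (self.mut_multiplier > 0):
            raise ScenarioValidationError(f + ".mut_multiplier", "must be > 0")
        if int(self.n_generations) != self.n_generations or self.n_generations < 1:
            raise ScenarioValidationError(f + ".n_generations", "must be an integer >= 1")


@dataclass(frozen=True)
class EnvParams:
    """Environmental regime.

    anomaly_sd
        SD (°C) of the i.i.d. Gaussian between-generation temperature anomaly
        (an ENSO-like basin-wide fluctuation, shared across populations).
    warming_rate
        linear temperature increase (°C per generation) after warming onset.
    burnin_stages
        staged pre-adaptation plan; smaller populations with proportionally
        higher mutation rates equilibrate faster while preserving N·mu.
    demography_lead
        number of generations before warming onset during which
        fitness-dependent demography is already active.
    warming_generations
        length of the warming period (the environment series is generated for
        the whole run up front; warming continues past any extinction).
    shared_anomaly
        if True (default) one anomaly draw per generation is applied to all
        populations; if False each population gets an independent draw.
    base_temp
        reference temperature (°C); by convention 0, the mild-regime optimum.
    """

    anomaly_sd: float = 0.25
    warming_rate: float = 0.05
    burnin_stages: tuple[BurninStage, ...] = (
        BurninStage(100, 100, 5000),
        BurninStage(10, 10, 5000),
        BurninStage(1, 1, 10000),
    )
    demography_lead: int = 500
    warming_generations: int = 200
    shared_anomaly: bool = True
    base_temp: float = 0.0

    def __post_init__(self):
        stages = tuple(
            s if isinstance(s, BurninStage) else BurninStage(*s) for s in self.burnin_stages
        )
        object.__setattr__(self, "burnin_stages", stages)

    @property
    def total_burnin(self) -> int:
        return sum(s.n_generations for s in self.burnin_stages)

    def validate(self) -> None:
        if not (self.anomaly_sd >= 0):
            raise ScenarioValidationError("environment.anomaly_sd", "must be >= 0")
        if not math.isfinite(self.warming_rate):
            raise ScenarioValidationError("environment.warming_rate", "must be finite")
        if not self.burnin_stages:
            raise ScenarioValidationError("environment.burnin_stages", "must be non-empty")
        for i, s in enumerate(self.burnin_stages):
            s.validate(i)
        # preserving N*mu across stages requires a constant multiplier/divisor ratio
        ratios = [s.mut_multiplier / s.size_divisor for s in self.burnin_stages]
        if any(abs(r - ratios[0]) > 1e-9 * max(1.0, abs(ratios[0])) for r in ratios):
            raise ScenarioValidationError(
                "environment.burnin_stages",
                "mut_multiplier/size_divisor must be equal across stages (preserves N*mu)",
            )
        if self.demography_lead < 0:
            raise ScenarioValidationError("environment.demography_lead", "must be >= 0")
        if self.demography_lead > self.burnin_stages[-1].n_generations:
            raise ScenarioValidationError(
                "environment.demography_lead",
                "must fit inside the final burn-in stage",
            )
        if self.warming_generations < 0:
            raise ScenarioValidationError("environment.warming_generations", "must be >= 0")


@dataclass(frozen=True)
class ScenarioConfig:
    """Complete description of one runnable experiment."""

    populations: tuple[PopulationSpec, ...]
    migration: MigrationMatrix
    genetics: GeneticParams
    environment: EnvParams
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "populations", tuple(self.populations))

    @property
    def n_populations(self) -> int:
        return len(self.populations)

    @property
    def names(self) -> list[str]:
        return [p.name for p in self.populations]

    @property
    def census_sizes(self) -> np.ndarray:
        return np.array([p.census_size for p in self.populations], dtype=int)

    @property
    def offsets(self) -> np.ndarray:
        return np.array([p.thermal_offset for p in self.populations], dtype=float)

    def validate(self) -> "ScenarioConfig":
        if not self.populations:
            raise ScenarioValidationError("populations", "must be non-empty")
        names = self.names
        if len(set(names)) != len(names):
            raise ScenarioValidationError("populations", "names must be unique")
        for p in self.populations:
            p.validate()
        self.migration.validate()
        if self.migration.n != self.n_populations:
            raise ScenarioValidationError(
                "migration.rates",
                f"dimension {self.migration.n} != number of populations {self.n_populations}",
            )
        self.genetics.validate()
        self.environment.validate()
        if int(self.seed) != self.seed:
            raise ScenarioValidationError("seed", "must be an integer")
        return self

    def replace(self, **kw) -> "ScenarioConfig":
        return dataclasses.replace(self, **kw).validate()


@dataclass(frozen=True)
class DadiEstimate:
    """Diffusion-scaled demographic estimates from AFS model fitting.

    theta = 4*Ne*mu (population-scaled mutation rate); t_split = divergence
    time in 2*Ne generations; m_scaled = 2*Ne*m; mu_frac = mutation rate per
    genotyped genome fraction per generation; gen_time = years per generation.
    """

    theta: float
    t_split: float
    m_scaled: float
    mu_frac: float = DEFAULT_MU_FRAC
    gen_time: float = DEFAULT_GEN_TIME

    def validate(self) -> None:
        for name in ("theta", "t_split", "m_scaled", "mu_frac", "gen_time"):
            if not (getattr(self, name) > 0):
                raise ScenarioValidationError(name, "must be > 0")

    def to_natural(self) -> tuple[float, float, float]:
        """Return (Ne individuals, per-generation migrant fraction m, time in years)."""
        self.validate()
        ne = ne_from_theta(self.theta, self.mu_frac)
        return ne, m_from_scaled(self.m_scaled, ne), years_from_scaled_time(
            self.t_split, ne, self.gen_time
        )


# ---------------------------------------------------------------------------
# Unit conversions
# ---------------------------------------------------------------------------


def ne_from_theta(theta: float, mu_frac: float = DEFAULT_MU_FRAC) -> float:
    """Ancestral effective population size, Ne = theta / (4 mu)."""
    if not (theta > 0):
        raise ValueError(f"theta must be > 0, got {theta}")
    if not (mu_frac > 0):
        raise ValueError(f"mu_frac must be > 0, got {mu_frac}")
    return theta / (4.0 * mu_frac)


def m_from_scaled(m_scaled: float, ne: float) -> float:
    """Per-generation immigrant fraction, m = M / (2 Ne)."""
    if not (ne > 0):
        raise ValueError(f"ne must be > 0, got {ne}")
    if m_scaled < 0:
        raise ValueError(f"m_scaled must be >= 0, got {m_scaled}")
    return m_scaled / (2.0 * ne)


def years_from_scaled_time(t_split: float, ne: float, gen_time: float = DEFAULT_GEN_TIME) -> float:
    """Divergence time in years, t = 2 T Ne * gen_time."""
    if not (t_split > 0 and ne > 0 and gen_time > 0):
        raise ValueError("t_split, ne and gen_time must all be > 0")
    return 2.0 * t_split * ne * gen_time


def matched_effect_sd(n_qtl_ref: int, effect_sd_ref: float, n_qtl_new: int) -> float:
    """Effect-size SD for ``n_qtl_new`` loci matching the total genetic variance
    of ``n_qtl_ref`` loci at ``effect_sd_ref`` (variance scales as n * sd^2)."""
    if n_qtl_ref < 1 or n_qtl_new < 1:
        raise ValueError("QTL counts must be >= 1")
    if not (effect_sd_ref > 0):
        raise ValueError("effect_sd_ref must be > 0")
    return effect_sd_ref * math.sqrt(n_qtl_ref / n_qtl_new)


# ---------------------------------------------------------------------------
# Scenario file I/O (YAML)
# ---------------------------------------------------------------------------

_TOP_KEYS = {"populations", "migration", "genetics", "environment", "seed"}
_POP_KEYS = {"name", "census_size", "thermal_offset"}
_MIG_KEYS = {"order", "rates"}
_GEN_KEYS = {"n_qtl", "effect_sd", "mut_rate", "esd", "sigma", "dominance"}
_ENV_KEYS = {
    "anomaly_sd",
    "warming_rate",
    "burnin_stages",
    "demography_lead",
    "warming_generations",
    "shared_anomaly",
    "base_temp",
}


def _require_keys(mapping: dict, allowed: set, where: str) -> None:
    if not isinstance(mapping, dict):
        raise ScenarioValidationError(where, f"expected a mapping, got {type(mapping).__name__}")
    unknown = set(mapping) - allowed
    if unknown:
        raise ScenarioValidationError(where, f"unknown keys: {sorted(unknown)}")


def scenario_from_dict(doc: dict) -> ScenarioConfig:
    """Build and validate a ScenarioConfig from a parsed mapping."""
    _require_keys(doc, _TOP_KEYS, "scenario")
    missing = _TOP_KEYS - {"seed"} - set(doc)
    if missing:
        raise ScenarioValidationError("scenario", f"missing keys: {sorted(missing)}")

    pops = []
    if not isinstance(doc["populations"], list):
        raise ScenarioValidationError("populations", "expected a list")
    for i, p in enumerate(doc["populations"]):
        _require_keys(p, _POP_KEYS, f"populations[{i}]")
        try:
            pops.append(
                PopulationSpec(
                    name=str(p["name"]),
                    census_size=int(p["census_size"]),
                    thermal_offset=float(p["thermal_offset"]),
                )
            )
        except KeyError as e:
            raise ScenarioValidationError(f"populations[{i}]", f"missing key {e}") from e
        except (TypeError, ValueError) as e:
            raise ScenarioValidationError(f"populations[{i}]", str(e)) from e

    mig = doc["migration"]
    _require_keys(mig, _MIG_KEYS, "migration")
    try:
        rates = np.asarray(mig["rates"], dtype=float)
    except (KeyError, TypeError, ValueError) as e:
        raise ScenarioValidationError("migration.rates", f"cannot parse: {e}") from e
    if "order" in mig:
        order = [str(x) for x in mig["order"]]
        names = [p.name for p in pops]
        if sorted(order) != sorted(names):
            raise ScenarioValidationError(
                "migration.order", f"{order} does not match population names {names}"
            )
        if order != names:  # permute source rows and destination columns to population order
            perm = [order.index(n) for n in names]
            rates = rates[np.ix_(perm, perm)]

    gen_doc = doc["genetics"]
    _require_keys(gen_doc, _GEN_KEYS, "genetics")
    try:
        genetics = GeneticParams(**{k: v for k, v in gen_doc.items()})
    except TypeError as e:
        raise ScenarioValidationError("genetics", str(e)) from e

    env_doc = doc["environment"]
    _require_keys(env_doc, _ENV_KEYS, "environment")
    env_kw = dict(env_doc)
    if "burnin_stages" in env_kw:
        stages = env_kw["burnin_stages"]
        if not isinstance(stages, list) or not all(
            isinstance(s, (list, tuple)) and len(s) == 3 for s in stages
        ):
            raise ScenarioValidationError(
                "environment.burnin_stages",
                "expected a list of [size_divisor, mut_multiplier, n_generations] triples",
            )
        env_kw["burnin_stages"] = tuple(
            BurninStage(float(a), float(b), int(c)) for a, b, c in stages
        )
    try:
        env = EnvParams(**env_kw)
    except TypeError as e:
        raise ScenarioValidationError("environment", str(e)) from e

    cfg = ScenarioConfig(
        populations=tuple(pops),
        migration=MigrationMatrix(rates),
        genetics=genetics,
        environment=env,
        seed=int(doc.get("seed", 0)),
    )
    return cfg.validate()


def scenario_to_dict(cfg: ScenarioConfig) -> dict:
    return {
        "populations": [
            {"name": p.name, "census_size": int(p.census_size), "thermal_offset": float(p.thermal_offset)}
            for p in cfg.populations
        ],
        "migration": {
            "order": cfg.names,
            "rates": [[float(x) for x in row] for row in cfg.migration.rates],
        },
        "genetics": {
            "n_qtl": int(cfg.genetics.n_qtl),
            "effect_sd": float(cfg.genetics.effect_sd),
            "mut_rate": float(cfg.genetics.mut_rate),
            "esd": float(cfg.genetics.esd),
            "sigma": float(cfg.genetics.sigma),
            "dominance": float(cfg.genetics.dominance),
        },
        "environment": {
            "anomaly_sd": float(cfg.environment.anomaly_sd),
            "warming_rate": float(cfg.environment.warming_rate),
            "burnin_stages": [
                [float(s.size_divisor), float(s.mut_multiplier), int(s.n_generations)]
                for s in cfg.environment.burnin_stages
            ],
            "demography_lead": int(cfg.environment.demography_lead),
            "warming_generations": int(cfg.environment.warming_generations),
            "shared_anomaly": bool(cfg.environment.shared_anomaly),
            "base_temp": float(cfg.environment.base_temp),
        },
        "seed": int(cfg.seed),
    }


def load_scenario(path: str | Path) -> ScenarioConfig:
    """Read and validate a scenario YAML file."""
    text = Path(path).read_text()
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as e:
        mark = getattr(e, "problem_mark", None)
        line = f" at line {mark.line + 1}" if mark is not None else ""
        raise ScenarioFormatError(f"cannot parse {path}{line}: {e}") from e
    if not isinstance(doc, dict):
        raise ScenarioFormatError(f"{path}: top level must be a mapping")
    return scenario_from_dict(doc)


def save_scenario(cfg: ScenarioConfig, path: str | Path) -> None:
    """Write a scenario as YAML; load_scenario(save_scenario(cfg)) round-trips."""
    Path(path).write_text(yaml.safe_dump(scenario_to_dict(cfg), sort_keys=False))


def packaged_scenario_path(name: str = "gbr") -> Path:
    """Filesystem path of a packaged example scenario."""
    res = importlib.resources.files("reefadapt") / "scenarios" / f"{name}.yaml"
    with importlib.resources.as_file(res) as p:
        return Path(p)


def load_packaged(name: str = "gbr") -> ScenarioConfig:
    """Load a packaged example scenario (default: the 5-population GBR reference)."""
    return load_scenario(packaged_scenario_path(name))


# ---------------------------------------------------------------------------
# Migration matrix TSV I/O
# ---------------------------------------------------------------------------


def migration_to_tsv(rates: np.ndarray, names: Sequence[str]) -> str:
    """Serialize a migration matrix as TSV with a header row/column of names."""
    lines = ["source\\dest\t" + "\t".join(names)]
    for i, name in enumerate(names):
        lines.append(name + "\t" + "\t".join(repr(float(x)) for x in rates[i]))
    return "\n".join(lines) + "\n"


def migration_from_tsv(text: str) -> tuple[np.ndarray, list[str]]:
    """Parse a TSV migration matrix; returns (rates, names)."""
    rows = [r.split("\t") for r in text.strip().splitlines()]
    names = rows[0][1:]
    rates = np.zeros((len(names), len(names)))
    for i, row in enumerate(rows[1:]):
        if row[0] != names[i]:
            raise ScenarioFormatError(
                f"migration TSV row label {row[0]!r} does not match header {names[i]!r}"
            )
        rates[i] = [float(x) for x in row[1:]]
    return rates, names


# ---------------------------------------------------------------------------
# Scaling and fixture helpers
# ---------------------------------------------------------------------------


def rescale_scenario(
    cfg: ScenarioConfig,
    size_divisor: float,
    burnin_stages: Sequence[tuple[float, float, int]] | None = None,
    demography_lead: int | None = None,
) -> ScenarioConfig:
    """Return a smaller, faster scenario that preserves N·mu.

    Census sizes are divided by ``size_divisor`` (floored at 2) and the
    mutation rate multiplied by the same factor, so the expected population
    mutational input — which sets the equilibrium amount of standing genetic
    variation — is unchanged.  Optionally replaces the burn-in plan and
    demography lead (shorter rescaled burn-ins equilibrate faster because the
    stage populations are proportionally smaller).
    """
    if not (size_divisor >= 1):
        raise ValueError("size_divisor must be >= 1")
    pops = tuple(
        dataclasses.replace(p, census_size=max(2, round(p.census_size / size_divisor)))
        for p in cfg.populations
    )
    genetics = dataclasses.replace(cfg.genetics, mut_rate=min(1.0, cfg.genetics.mut_rate * size_divisor))
    env_kw: dict = {}
    if burnin_stages is not None:
        env_kw["burnin_stages"] = tuple(BurninStage(*s) for s in burnin_stages)
    if demography_lead is not None:
        env_kw["demography_lead"] = demography_lead
    env = dataclasses.replace(cfg.environment, **env_kw) if env_kw else cfg.environment
    return dataclasses.replace(cfg, populations=pops, genetics=genetics, environment=env).validate()


def random_scenario(rng: np.random.Generator, max_pops: int = 5) -> ScenarioConfig:
    """Generate a random valid scenario (test fixture generator)."""
    k = int(rng.integers(1, max_pops + 1))
    pops = tuple(
        PopulationSpec(
            name=f"P{i}",
            census_size=int(rng.integers(10, 500)),
            thermal_offset=float(np.round(rng.normal(0, 1.0), 3)),
        )
        for i in range(k)
    )
    rates = rng.uniform(0, 0.01, size=(k, k))
    np.fill_diagonal(rates, 0.0)
    genetics = GeneticParams(
        n_qtl=int(rng.integers(1, 20)),
        effect_sd=float(rng.uniform(0.05, 0.5)),
        mut_rate=float(10.0 ** rng.uniform(-7, -3)),
        esd=float(rng.uniform(0, 2)),
        sigma=float(rng.uniform(0.3, 3)),
        dominance=0.5,
    )
    n1, n2 = int(rng.integers(5, 50)), int(rng.integers(10, 100))
    env = EnvParams(
        anomaly_sd=float(rng.uniform(0, 0.5)),
        warming_rate=float(rng.uniform(0, 0.1)),
        burnin_stages=(BurninStage(10, 10, n1), BurninStage(1, 1, n2)),
        demography_lead=int(rng.integers(0, n2 // 2 + 1)),
        warming_generations=int(rng.integers(1, 50)),
    )
    cfg = ScenarioConfig(
        populations=pops,
        migration=MigrationMatrix(rates),
        genetics=genetics,
        environment=env,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    return cfg.validate()
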