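"""Per-generation, per-population realized temperatures.

The temperature experienced by population *p* in generation *t* is

    T[t, p] = base + offset_p + anomaly[t] + warming_rate * max(0, t - onset)

where ``anomaly`` is an i.i.d. Gaussian draw shared by all populations within
a generation (a basin-wide ENSO-like fluctuation) and the linear ramp starts
at the warming onset.  All temperatures are anomalies relative to the
mild-regime populations' optimum (base = 0 by convention).
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .config import EnvParams, PopulationSpec

__all__ = ["EnvSeries", "generate_env", "rate_from_decadal", "env_to_tsv", "env_from_tsv"]


@dataclass(frozen=True)
class EnvSeries:
    """Realized temperature series.

    temps
        (n_generations, n_populations) array of °C.
    anomaly
        (n_generations,) shared anomaly (NaN-filled if per-population
        independent anomalies were requested).
    warming_onset
        generation index at which the linear ramp starts.
    names
        population labels (column order of ``temps``).
    """

    temps: np.ndarray
    anomaly: np.ndarray
    warming_onset: int
    names: tuple[str, ...]

    @property
    def n_generations(self) -> int:
        return self.temps.shape[0]


def generate_env(
    env: EnvParams,
    populations: Sequence[PopulationSpec],
    n_generations: int,
    rng_seed: int | np.random.SeedSequence,
    warming_onset: int | None = None,
) -> EnvSeries:
    """Generate the realized temperature series for a run.

    Deterministic given ``rng_seed``.  ``warming_onset`` defaults to the end
    of the burn-in plan.  The series has fixed length: warming continues past
    any extinction.
    """
    if n_generations < 1:
        raise ValueError("n_generations must be >= 1")
    rng = np.random.default_rng(rng_seed)
    onset = env.total_burnin if warming_onset is None else int(warming_onset)
    offsets = np.array([p.thermal_offset for p in populations], dtype=float)
    t = np.arange(n_generations, dtype=float)
    ramp = env.warming_rate * np.maximum(0.0, t - onset)
    if env.shared_anomaly:
        anomaly = rng.normal(0.0, env.anomaly_sd, size=n_generations)
        temps = env.base_temp + offsets[None, :] + (anomaly + ramp)[:, None]
    else:
        draws = rng.normal(0.0, env.anomaly_sd, size=(n_generations, len(populations)))
        anomaly = np.full(n_generations, np.nan)
        temps = env.base_temp + offsets[None, :] + draws + ramp[:, None]
    return EnvSeries(
        temps=temps,
        anomaly=anomaly,
        warming_onset=onset,
        names=tuple(p.name for p in populations),
    )


def rate_from_decadal(decadal_rate: float, gen_time: float) -> float:
    """Convert °C per decade into °C per generation (gen_time in years)."""
    if not (gen_time > 0):
        raise ValueError("gen_time must be > 0")
    return decadal_rate * gen_time / 10.0


def env_to_tsv(series: EnvSeries, path: str | Path | None = None) -> str:
    """Serialize as TSV: generation column plus one temperature column per population."""
    df = pd.DataFrame(series.temps, columns=list(series.names))
    df.insert(0, "generation", np.arange(series.n_generations))
    text = df.to_csv(sep="\t", index=False, float_format="%.17g")
    if path is not None:
        Path(path).write_text(text)
    return text


def env_from_tsv(source: str | Path, warming_onset: int = 0) -> EnvSeries:
    """Read a user-supplied temperature table (bypasses generate_env).

    The anomaly column is not recoverable from a raw table and is NaN.
    """
    is_path = isinstance(source, Path) or (
        isinstance(source, str) and "\n" not in source and "\t" not in source
    )
    df = pd.read_csv(Path(source) if is_path else io.StringIO(str(source)), sep="\t")
    names = tuple(c for c in df.columns if c != "generation")
    temps = df[list(names)].to_numpy(dtype=float)
    return EnvSeries(
        temps=temps,
        anomaly=np.full(temps.shape[0], np.nan),
        warming_onset=warming_onset,
        names=names,
    )
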