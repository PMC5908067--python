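"""Per-generation observables: mean fitness, mean breeding value, genetic
variation, census sizes, and anomaly-sensitivity diagnostics.

Mean fitness is reported relative to 1, the maximum attainable with perfect
heritability (the unnormalized Gaussian tolerance curve peaks at 1 when the
phenotype matches the environment exactly).  Genetic variation is the
standard deviation of breeding values across individuals — the average
difference, in °C, between an individual's genetically determined thermal
optimum and the population mean.  Metapopulation-level variation pools the
individuals of all extant populations.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

__all__ = [
    "PopTrace",
    "MetaTrace",
    "TraceCollector",
    "summarize_generation",
    "anomaly_sensitivity",
]

TRACE_COLUMNS = [
    "generation",
    "population",
    "mean_fitness",
    "mean_breeding",
    "genetic_sd",
    "census",
    "env_temp",
]


@dataclass(frozen=True)
class PopTrace:
    """Tidy per-generation, per-population trace.

    ``df`` has columns generation, population, mean_fitness, mean_breeding,
    genetic_sd, census, env_temp; extinct populations have census 0 and
    missing statistics.
    """

    df: pd.DataFrame

    @classmethod
    def empty(cls, names: Sequence[str]) -> "PopTrace":
        return cls(pd.DataFrame(columns=TRACE_COLUMNS))

    @property
    def populations(self) -> list[str]:
        return list(dict.fromkeys(self.df["population"]))

    def for_population(self, name: str) -> pd.DataFrame:
        return self.df[self.df["population"] == name].reset_index(drop=True)

    def pivot(self, column: str) -> pd.DataFrame:
        """Wide view: generations × populations for one metric."""
        return self.df.pivot(index="generation", columns="population", values=column)

    def to_tsv(self, path: str | Path | None = None) -> str:
        text = self.df.to_csv(sep="\t", index=False, float_format="%.17g")
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_tsv(cls, source: str | Path) -> "PopTrace":
        is_path = isinstance(source, Path) or (
            isinstance(source, str) and "\n" not in source and "\t" not in source
        )
        df = pd.read_csv(
            Path(source) if is_path else io.StringIO(str(source)),
            sep="\t",
            dtype={"population": str},
        )
        df = df.astype(
            {
                "generation": "int64",
                "census": "int64",
                "mean_fitness": "float64",
                "mean_breeding": "float64",
                "genetic_sd": "float64",
                "env_temp": "float64",
            }
        )
        return cls(df[TRACE_COLUMNS])


@dataclass(frozen=True)
class MetaTrace:
    """Pooled metapopulation trace: generation, pooled genetic SD, the law-of-
    total-variance components, and total census."""

    df: pd.DataFrame

    @classmethod
    def empty(cls) -> "MetaTrace":
        return cls(
            pd.DataFrame(
                columns=["generation", "pooled_sd", "within_var", "between_var", "census"]
            )
        )

    def to_tsv(self, path: str | Path | None = None) -> str:
        text = self.df.to_csv(sep="\t", index=False, float_format="%.17g")
        if path is not None:
            Path(path).write_text(text)
        return text


def summarize_generation(
    generation: int,
    names: Sequence[str],
    breeding_by_pop: Sequence[np.ndarray | None],
    fitness_by_pop: Sequence[np.ndarray | None],
    census: np.ndarray,
    env_row: np.ndarray,
) -> tuple[list[dict], dict]:
    """Compute one generation's trace rows plus the pooled metapopulation row.

    Population-style (ddof=0) variances are used so the pooled variance
    decomposes exactly into mean within-population variance plus
    size-weighted between-population variance of means.
    """
    rows = []
    pooled: list[np.ndarray] = []
    for p_idx, name in enumerate(names):
        bv, w = breeding_by_pop[p_idx], fitness_by_pop[p_idx]
        if bv is None or census[p_idx] == 0:
            rows.append(
                dict(
                    generation=generation,
                    population=name,
                    mean_fitness=np.nan,
                    mean_breeding=np.nan,
                    genetic_sd=np.nan,
                    census=0,
                    env_temp=float(env_row[p_idx]),
                )
            )
            continue
        pooled.append(bv)
        rows.append(
            dict(
                generation=generation,
                population=name,
                mean_fitness=float(np.mean(w)),
                mean_breeding=float(np.mean(bv)),
                genetic_sd=float(np.std(bv)),
                census=int(census[p_idx]),
                env_temp=float(env_row[p_idx]),
            )
        )
    if pooled:
        allbv = np.concatenate(pooled)
        sizes = np.array([len(b) for b in pooled], dtype=float)
        means = np.array([b.mean() for b in pooled])
        wvar = float(np.sum([b.var() * len(b) for b in pooled]) / sizes.sum())
        bvar = float(np.sum(sizes * (means - allbv.mean()) ** 2) / sizes.sum())
        meta = dict(
            generation=generation,
            pooled_sd=float(np.std(allbv)),
            within_var=wvar,
            between_var=bvar,
            census=int(sizes.sum()),
        )
    else:
        meta = dict(
            generation=generation, pooled_sd=np.nan, within_var=np.nan, between_var=np.nan, census=0
        )
    return rows, meta


class TraceCollector:
    """Accumulates per-generation rows and finalizes into (PopTrace, MetaTrace)."""

    def __init__(self, names: Sequence[str]):
        self.names = list(names)
        self._rows: list[dict] = []
        self._meta: list[dict] = []

    def add(self, generation, breeding_by_pop, fitness_by_pop, census, env_row) -> None:
        rows, meta = summarize_generation(
            generation, self.names, breeding_by_pop, fitness_by_pop, census, env_row
        )
        self._rows.extend(rows)
        self._meta.append(meta)

    def finalize(self) -> tuple[PopTrace, MetaTrace]:
        return PopTrace(pd.DataFrame(self._rows, columns=TRACE_COLUMNS)), MetaTrace(
            pd.DataFrame(self._meta)
        )


def anomaly_sensitivity(
    trace: PopTrace,
    anomaly: np.ndarray,
    population: str,
    start: int | None = None,
    stop: int | None = None,
    smoothing_span: float = 0.2,
    amplitude_window: int = 20,
) -> pd.DataFrame:
    """Fitness residuals from a local-regression smooth, paired with anomalies.

    Detrends a population's mean-fitness trace with lowess (span as a fraction
    of the analyzed window) and returns, per generation: the residual, the
    sign-inverted temperature anomaly (so a hot year plots in the same
    direction as the fitness drop it causes), and a rolling residual-amplitude
    (windowed SD) series that tracks how sensitive the population is to
    thermal fluctuations.
    """
    sub = trace.for_population(population)
    gen = sub["generation"].to_numpy()
    start = int(gen[0]) if start is None else start
    stop = int(gen[-1]) + 1 if stop is None else stop
    mask = (gen >= start) & (gen < stop) & sub["mean_fitness"].notna().to_numpy()
    g = gen[mask]
    f = sub["mean_fitness"].to_numpy()[mask]
    span_points = max(3, int(round(smoothing_span * len(g))))
    if len(g) < span_points:
        raise ValueError(
            f"series of length {len(g)} is shorter than the smoothing span ({span_points} points)"
        )
    smooth = lowess(f, g, frac=smoothing_span, return_sorted=False)
    resid = f - smooth
    amp = (
        pd.Series(resid)
        .rolling(amplitude_window, min_periods=max(2, amplitude_window // 2))
        .std()
        .to_numpy()
    )
    return pd.DataFrame(
        {
            "generation": g,
            "fitness_residual": resid,
            "anomaly_inverted": -np.asarray(anomaly)[g],
            "residual_amplitude": amp,
        }
    )
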