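"""Genetic state and Mendelian machinery.

Each individual carries two haplotypes, each a vector of continuous allelic
effects (°C) at ``n_qtl`` unlinked loci (continuum-of-alleles: a new mutation
adds a Gaussian increment to the existing allelic value, so a single real
number per haplotype per locus captures the full mutational history).  The
breeding value is the sum of allelic effects over loci and haplotypes; the
phenotype — the individual's thermal optimum — adds Gaussian non-heritable
noise of SD ``esd``.

Gametes segregate freely: at every locus one of the parent's two allelic
values is chosen with probability 1/2, then mutated with probability
``mut_rate`` by an N(0, effect_sd) increment.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "HaplotypeState",
    "PhenotypeVector",
    "breeding_values",
    "phenotypes",
    "make_gamete",
    "make_gametes",
    "state_to_tsv",
    "state_from_tsv",
]


@dataclass
class HaplotypeState:
    """Full genetic state of one population.

    values
        (n_individuals, 2, n_qtl) array of allelic effects in °C.
    """

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or self.values.shape[1] != 2:
            raise ValueError("values must have shape (n_individuals, 2, n_qtl)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("allelic values must be finite")

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_qtl(self) -> int:
        return self.values.shape[2]

    @classmethod
    def founders(cls, n_individuals: int, n_qtl: int) -> "HaplotypeState":
        """Monomorphic founding population (all allelic effects zero)."""
        return cls(np.zeros((n_individuals, 2, n_qtl)))


@dataclass(frozen=True)
class PhenotypeVector:
    """Per-individual breeding values and phenotypes (°C)."""

    breeding: np.ndarray
    phenotype: np.ndarray


def breeding_values(state: HaplotypeState, dominance: float = 0.5) -> np.ndarray:
    """Per-individual breeding value: the genetic thermal optimum in °C.

    At dominance h = 0.5 (additive) this is the plain sum of both haplotypes'
    allelic values over all loci.  For h != 0.5 the per-locus genotypic value
    weights the larger-magnitude allele: with a_min/a_max the smaller/larger
    magnitude allelic values at a locus,

        value(locus) = a_min + 2 h (a_max - a_min)

    which reduces to a_min + a_max at h = 0.5, to a_min alone at h = 0 (the
    larger-magnitude allele fully recessive) and to 2*a_max - a_min at h = 1.
    Only h = 0.5 is used in the shipped scenarios; other values are
    experimental.
    """
    if not (0.0 <= dominance <= 1.0):
        raise ValueError("dominance must be in [0, 1]")
    v = state.values
    if dominance == 0.5:
        return v.sum(axis=(1, 2))
    mag_order = np.abs(v).argsort(axis=1)  # per locus: index 0 = smaller magnitude
    a_sorted = np.take_along_axis(v, mag_order, axis=1)
    a_min, a_max = a_sorted[:, 0, :], a_sorted[:, 1, :]
    per_locus = a_min + 2.0 * dominance * (a_max - a_min)
    return per_locus.sum(axis=1)


def phenotypes(
    breeding: np.ndarray, esd: float, rng: np.random.Generator
) -> PhenotypeVector:
    """Add N(0, esd) non-heritable noise to breeding values.

    esd = 0 is heritability 1: the phenotype equals the breeding value exactly
    (no random draws are consumed, keeping the rng stream comparable across
    esd settings).
    """
    breeding = np.asarray(breeding, dtype=float)
    if esd < 0:
        raise ValueError("esd must be >= 0")
    if esd == 0:
        return PhenotypeVector(breeding=breeding, phenotype=breeding.copy())
    noise = rng.normal(0.0, esd, size=breeding.shape)
    return PhenotypeVector(breeding=breeding, phenotype=breeding + noise)


def make_gametes(
    state: HaplotypeState,
    parent_indices: np.ndarray,
    mut_rate: float,
    effect_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Form one gamete per entry of ``parent_indices`` (vectorized).

    For each gamete and each locus independently, one of the parent's two
    allelic values is chosen with probability 1/2 (free recombination); with
    probability ``mut_rate`` an N(0, effect_sd) increment is then added.
    Returns an array of shape parent_indices.shape + (n_qtl,).
    """
    parent_indices = np.asarray(parent_indices)
    pv = state.values[parent_indices]  # (..., 2, L)
    shape = parent_indices.shape + (state.n_qtl,)
    pick = rng.integers(0, 2, size=shape)
    gam = np.take_along_axis(pv, pick[..., None, :], axis=-2)[..., 0, :]
    if mut_rate > 0:
        hits = rng.random(shape) < mut_rate
        n_hits = int(hits.sum())
        if n_hits:
            gam[hits] += rng.normal(0.0, effect_sd, size=n_hits)
    return gam


def make_gamete(
    state: HaplotypeState,
    parent_index: int,
    mut_rate: float,
    effect_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Single-gamete convenience wrapper around :func:`make_gametes`."""
    if not (0 <= parent_index < state.n_individuals):
        raise IndexError(f"parent_index {parent_index} out of range")
    return make_gametes(state, np.array([parent_index]), mut_rate, effect_sd, rng)[0]


def state_to_tsv(state: HaplotypeState, path: str | Path) -> None:
    """Checkpoint the full genetic state as TSV (individual, haplotype, per-locus columns)."""
    n, _, L = state.values.shape
    flat = state.values.reshape(n * 2, L)
    df = pd.DataFrame(flat, columns=[f"qtl{j}" for j in range(L)])
    df.insert(0, "haplotype", np.tile([0, 1], n))
    df.insert(0, "individual", np.repeat(np.arange(n), 2))
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def state_from_tsv(path: str | Path) -> HaplotypeState:
    """Restore a checkpointed genetic state."""
    df = pd.read_csv(path, sep="\t")
    qtl_cols = [c for c in df.columns if c.startswith("qtl")]
    n = df["individual"].nunique()
    values = df[qtl_cols].to_numpy(dtype=float).reshape(n, 2, len(qtl_cols))
    return HaplotypeState(values)
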