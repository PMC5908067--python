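"""Forward simulation of unlinked neutral biallelic loci under arbitrary
population-size trajectories, and site-frequency-spectrum utilities.

Loci are simulated as independent derived-allele-frequency trajectories: each
generation the derived count at a locus is a Binomial(2N(t), p) draw — exact
for unlinked neutral loci in a Wright-Fisher population and orders of
magnitude faster than tracking individuals.  Monomorphic loci gain a single
derived copy with probability 2N(t)·mu per generation (no recurrent mutation
at already-polymorphic loci, a good approximation for short RAD-tag SNPs).

The headline use is the decline-detectability experiment: 2bRAD-like tag loci
in a population that declines exponentially over its last 20 generations, a
sample of diploids taken at the end, and the unfolded spectrum written in a
single-population AFS text format that demographic-inference tools consume.
The upstream signal of a decline in the spectrum is depletion of rare
alleles (a reduced singleton fraction).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.stats import hypergeom

__all__ = [
    "NeutralSimSpec",
    "SFS",
    "exponential_trajectory",
    "simulate_neutral",
    "project_sfs",
    "write_sfs",
    "read_sfs",
]


@dataclass(frozen=True)
class SFS:
    """Unfolded allele-frequency spectrum of a sample of n diploids.

    ``counts[k]`` = number of loci with k derived copies among the 2n sampled
    chromosomes (length 2n+1; classes 0 and 2n are the non-segregating
    ancestral-fixed and derived-fixed classes).
    """

    counts: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.counts, dtype=float)
        if c.ndim != 1 or len(c) < 3 or (len(c) - 1) % 2 != 0:
            raise ValueError("counts must have length 2n+1 for n diploids")
        if np.any(c < 0):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", c)

    @property
    def n_diploids(self) -> int:
        return (len(self.counts) - 1) // 2

    @property
    def n_chromosomes(self) -> int:
        return len(self.counts) - 1

    def segregating(self) -> np.ndarray:
        """Counts of the segregating classes 1 .. 2n-1."""
        return self.counts[1:-1]

    @property
    def n_segregating(self) -> float:
        return float(self.segregating().sum())

    @property
    def singleton_fraction(self) -> float:
        """Fraction of segregating sites that are singletons."""
        s = self.n_segregating
        return float(self.counts[1] / s) if s > 0 else float("nan")


@dataclass(frozen=True)
class NeutralSimSpec:
    """Specification of one neutral simulation.

    n_loci
        number of unlinked biallelic tag loci.
    trajectory
        per-generation diploid population sizes N(t), first entry = initial.
    theta_per_locus
        population-scaled mutation rate 4*N0*mu per locus; sets both the
        stationary initialization and the per-generation mutational influx.
    sample_size
        diploids sampled (without replacement) from the final generation.
    equilibrium_start
        if True (default) initial derived counts are drawn from the neutral
        stationary spectrum (P(count=k) ∝ theta/k); if False all loci start
        monomorphic ancestral.
    init_theta
        theta used for the stationary initialization when it should differ
        from the influx theta (e.g. mutation-free drift from an equilibrium
        standing state); defaults to ``theta_per_locus``.
    """

    n_loci: int
    trajectory: np.ndarray
    theta_per_locus: float = 0.05
    sample_size: int = 84
    equilibrium_start: bool = True
    init_theta: float | None = None

    def __post_init__(self):
        traj = np.asarray(self.trajectory, dtype=int)
        if traj.ndim != 1 or len(traj) < 1 or np.any(traj < 1):
            raise ValueError("trajectory must be a positive 1-D size series")
        object.__setattr__(self, "trajectory", traj)
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        if self.theta_per_locus < 0:
            raise ValueError("theta_per_locus must be >= 0")
        if not (1 <= self.sample_size <= traj[-1]):
            raise ValueError(
                f"sample_size {self.sample_size} must be in [1, final size {traj[-1]}]"
            )


def exponential_trajectory(
    n0: int,
    fraction: float,
    n_decline_generations: int,
    n_stable_generations: int = 0,
) -> np.ndarray:
    """Diploid size series: stable at n0, then exponential decay to n0*fraction.

    N(t) = n0 * fraction^(t / n_decline_generations) over the decline,
    rounded; fraction = 1 gives a constant-size control.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    if n_decline_generations < 0 or n_stable_generations < 0:
        raise ValueError("generation counts must be >= 0")
    stable = np.full(n_stable_generations + 1, n0, dtype=int)
    if n_decline_generations == 0:
        return stable
    t = np.arange(1, n_decline_generations + 1, dtype=float)
    decline = np.round(n0 * fraction ** (t / n_decline_generations)).astype(int)
    return np.concatenate([stable, decline])


def _stationary_init(
    n_loci: int, n0: int, theta: float, rng: np.random.Generator
) -> np.ndarray:
    """Initial derived counts drawn from the neutral stationary spectrum.

    Under mutation-drift balance the expected number of loci with k of 2N
    derived copies is theta/k; the remaining loci are monomorphic ancestral.
    """
    counts = np.zeros(n_loci, dtype=np.int64)
    if theta <= 0:
        return counts
    k = np.arange(1, 2 * n0)
    weights = theta / k
    p_poly = min(1.0, weights.sum())
    poly = rng.random(n_loci) < p_poly
    n_poly = int(poly.sum())
    if n_poly:
        counts[poly] = rng.choice(k, size=n_poly, p=weights / weights.sum())
    return counts


def simulate_neutral(spec: NeutralSimSpec, rng: np.random.Generator) -> SFS:
    """Evolve the loci along the size trajectory and return the sample SFS.

    Per generation: binomial resampling of each locus's derived count out of
    2N(t) chromosomes; monomorphic-ancestral loci gain one derived copy with
    probability 2N(t)*mu (mu = theta/(4 N0)).  The final sample of
    ``sample_size`` diploids is drawn hypergeometrically (2*sample_size
    chromosomes without replacement).
    """
    traj = spec.trajectory
    n0 = int(traj[0])
    mu = spec.theta_per_locus / (4.0 * n0)
    theta0 = spec.theta_per_locus if spec.init_theta is None else spec.init_theta
    counts = (
        _stationary_init(spec.n_loci, n0, theta0, rng)
        if spec.equilibrium_start
        else np.zeros(spec.n_loci, dtype=np.int64)
    )
    n_prev = n0
    for n_now in traj[1:]:
        two_n_prev, two_n = 2 * int(n_prev), 2 * int(n_now)
        p = counts / two_n_prev
        counts = rng.binomial(two_n, p)
        if mu > 0:
            mono = counts == 0
            hits = mono & (rng.random(spec.n_loci) < two_n * mu)
            counts[hits] = 1
        n_prev = n_now
    # sample 2*sample_size chromosomes without replacement from the final pool
    two_n_final = 2 * int(traj[-1])
    two_s = 2 * spec.sample_size
    sampled = rng.hypergeometric(counts, two_n_final - counts, two_s)
    sfs = np.bincount(sampled, minlength=two_s + 1).astype(float)
    return SFS(sfs)


def project_sfs(sfs: SFS, target_n: int) -> SFS:
    """Expected down-projection of an SFS to a smaller diploid sample size.

    Each class k of 2n chromosomes is redistributed over classes j of 2m
    chromosomes with hypergeometric weights P(j | k); class totals are
    conserved.  Projection to the same n is the identity.
    """
    n = sfs.n_diploids
    if target_n > n:
        raise ValueError(f"cannot project up: target_n {target_n} > sample n {n}")
    if target_n < 1:
        raise ValueError("target_n must be >= 1")
    if target_n == n:
        return SFS(sfs.counts.copy())
    big, small = 2 * n, 2 * target_n
    out = np.zeros(small + 1)
    j = np.arange(small + 1)
    for k in range(big + 1):
        if sfs.counts[k] == 0:
            continue
        out += sfs.counts[k] * hypergeom.pmf(j, big, k, small)
    return SFS(out)


def write_sfs(sfs: SFS, path: str | Path, dialect: str = "dadi", label: str = "pop1") -> None:
    """Write a single-population unfolded SFS.

    dialect="dadi": three lines — "<2n+1> unfolded <label>", the space-
    separated counts, and a mask row (1 = masked) masking the fixed classes 0
    and 2n by default.  dialect="tsv": two columns (derived_copies, n_loci).
    """
    p = Path(path)
    if dialect == "dadi":
        dim = len(sfs.counts)
        mask = np.zeros(dim, dtype=int)
        mask[0] = mask[-1] = 1
        lines = [
            f"{dim} unfolded {label}",
            " ".join(format(c, ".10g") for c in sfs.counts),
            " ".join(str(m) for m in mask),
        ]
        p.write_text("\n".join(lines) + "\n")
    elif dialect == "tsv":
        lines = ["derived_copies\tn_loci"] + [
            f"{k}\t{format(c, '.10g')}" for k, c in enumerate(sfs.counts)
        ]
        p.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_sfs(path: str | Path, dialect: str = "dadi") -> SFS:
    """Read an SFS written by :func:`write_sfs`."""
    text = Path(path).read_text().strip().splitlines()
    if dialect == "dadi":
        dim = int(text[0].split()[0])
        counts = np.array([float(x) for x in text[1].split()])
        if len(counts) != dim:
            raise ValueError(f"dimension line says {dim} but {len(counts)} counts found")
        return SFS(counts)
    if dialect == "tsv":
        counts = np.array([float(line.split("\t")[1]) for line in text[1:]])
        return SFS(counts)
    raise ValueError(f"unknown dialect {dialect!r}")
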