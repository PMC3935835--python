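"""Wright-Fisher dynamics of a mutagenized founder population.

Motivates non-competitive screening: if independently mutagenized strains
are grown together, selection plus drift rapidly collapses the pool onto
one or a few winners, hiding most genetic causes of a phenotype. Founder
strains (one cell each) double deterministically until the culture reaches
carrying capacity, after which each generation is a multinomial resample
of the fixed-size population with probabilities proportional to
count x fitness. Diversity is tracked as the number of distinct surviving
strains and the Shannon entropy (bits) of the strain distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

log = logging.getLogger(__name__)


@dataclass
class WFConfig:
    """Simulation setup.

    ``fitnesses`` fixes per-strain relative fitnesses; when ``None``,
    each replicate draws fresh lognormal(0, fitness_sigma) fitnesses — a
    documented stand-in, since real fitness distributions of mutagenized
    strains are rarely known. ``fitness_sigma = 0`` gives neutral drift.
    """

    n_strains: int = 26
    carrying_capacity: int = 1_000_000
    n_generations: int = 30
    n_replicates: int = 1000
    fitnesses: Sequence[float] | None = None
    fitness_sigma: float = 0.3
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_strains < 1:
            raise ValueError("n_strains must be >= 1")
        if self.carrying_capacity < self.n_strains:
            raise ValueError("carrying_capacity must be >= n_strains")
        if self.fitnesses is not None:
            f = np.asarray(self.fitnesses, dtype=float)
            if len(f) != self.n_strains:
                raise ValueError("fitnesses must have one value per strain")
            if np.any(f <= 0):
                raise ValueError("fitnesses must be > 0")
        if self.fitness_sigma < 0:
            raise ValueError("fitness_sigma must be >= 0")


@dataclass
class WFTrajectory:
    """Per-generation record of one replicate (generation 0 = founders)."""

    counts: np.ndarray  # (n_generations + 1, n_strains)
    n_distinct: np.ndarray
    entropy: np.ndarray


@dataclass
class WFSummary:
    """Replicate-averaged diversity trajectories."""

    mean_n_distinct: np.ndarray
    mean_entropy: np.ndarray
    half_diversity_generation: int | None
    n_replicates: int
    capacity_generation: int


def shannon_entropy(proportions: Sequence[float]) -> float:
    """Shannon entropy in bits, with 0 * log 0 := 0."""
    p = np.asarray(proportions, dtype=float)
    if np.any(p < 0):
        raise ValueError("proportions must be nonnegative")
    if not np.isclose(p.sum(), 1.0):
        raise ValueError(f"proportions must sum to 1, got {p.sum()}")
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def wf_step(
    counts: np.ndarray,
    fitnesses: np.ndarray,
    pop_size: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """One generation: multinomial resampling weighted by count x fitness.

    Strains at zero stay at zero (no back-mutation); a single surviving
    strain is an absorbing state.
    """
    counts = np.asarray(counts)
    if counts.sum() == 0:
        raise ValueError("population is extinct (all counts zero)")
    w = counts * np.asarray(fitnesses, dtype=float)
    return rng.multinomial(pop_size, w / w.sum())


def simulate_trajectory(
    n_strains: int,
    fitnesses: np.ndarray,
    carrying_capacity: int,
    n_generations: int,
    rng: np.random.Generator,
) -> WFTrajectory:
    """One replicate: deterministic doubling to capacity, then WF resampling."""
    counts = np.ones(n_strains, dtype=np.int64)
    traj = np.empty((n_generations + 1, n_strains), dtype=np.int64)
    traj[0] = counts
    at_capacity = counts.sum() >= carrying_capacity
    for g in range(1, n_generations + 1):
        if not at_capacity:
            counts = counts * 2
            if counts.sum() >= carrying_capacity:
                # trim the overshoot down to exactly the capacity
                counts = rng.multinomial(carrying_capacity, counts / counts.sum())
                at_capacity = True
        else:
            counts = wf_step(counts, fitnesses, carrying_capacity, rng)
        traj[g] = counts
    n_distinct = (traj > 0).sum(axis=1)
    totals = traj.sum(axis=1)
    entropy = np.array(
        [shannon_entropy(row / tot) for row, tot in zip(traj, totals)]
    )
    return WFTrajectory(counts=traj, n_distinct=n_distinct, entropy=entropy)


def capacity_generation(n_strains: int, carrying_capacity: int) -> int:
    """First generation at which doubling founders reaches capacity."""
    g = 0
    total = n_strains
    while total < carrying_capacity:
        total *= 2
        g += 1
    return g


def simulate(cfg: WFConfig) -> WFSummary:
    """Replicate-averaged diversity loss; seed-reproducible.

    The half-diversity generation is the first generation at which the
    mean distinct-strain count drops to half the founder count (``None``
    if never reached within the horizon).
    """
    rng = np.random.default_rng(cfg.seed)
    sum_distinct = np.zeros(cfg.n_generations + 1)
    sum_entropy = np.zeros(cfg.n_generations + 1)
    for _ in range(cfg.n_replicates):
        if cfg.fitnesses is not None:
            fit = np.asarray(cfg.fitnesses, dtype=float)
        elif cfg.fitness_sigma == 0:
            fit = np.ones(cfg.n_strains)
        else:
            fit = rng.lognormal(mean=0.0, sigma=cfg.fitness_sigma, size=cfg.n_strains)
        traj = simulate_trajectory(
            cfg.n_strains, fit, cfg.carrying_capacity, cfg.n_generations, rng
        )
        sum_distinct += traj.n_distinct
        sum_entropy += traj.entropy
    mean_distinct = sum_distinct / cfg.n_replicates
    mean_entropy = sum_entropy / cfg.n_replicates
    half = np.nonzero(mean_distinct <= cfg.n_strains / 2)[0]
    return WFSummary(
        mean_n_distinct=mean_distinct,
        mean_entropy=mean_entropy,
        half_diversity_generation=int(half[0]) if half.size else None,
        n_replicates=cfg.n_replicates,
        capacity_generation=capacity_generation(cfg.n_strains, cfg.carrying_capacity),
    )
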