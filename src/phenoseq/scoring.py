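"""The phenotype-sequencing scoring core.

Under neutral chemical mutagenesis, mutations land on the genome with
per-site densities that differ between G/C and A/T sites (NTG, the mutagen
emulated here, hits G/C sites overwhelmingly). The expected mutational
cross-section of a gene or gene group is then

    lambda = gc_sites * rho_gc + at_sites * rho_at,

with the densities rho estimated genome-wide from the observed mutation
set. A unit observed with n nonsynonymous mutations is scored by the
Poisson upper tail P(X >= n | X ~ Poisson(lambda)), Bonferroni-corrected
by the number of units tested. A group hit far more often than its
cross-section predicts is a candidate cause of the screened phenotype.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from scipy.stats import poisson

from .annotation import AnnotatedMutation
from .pathways import MutationTally

log = logging.getLogger(__name__)

DENSITY_MODES = ("nonsynonymous", "all")


@dataclass(frozen=True)
class SiteDensities:
    """Genome-wide per-site mutation densities on G/C vs A/T sites."""

    rho_gc: float
    rho_at: float
    n_mutations_used: int
    mode: str

    def __post_init__(self) -> None:
        if self.rho_gc < 0 or self.rho_at < 0:
            raise ValueError("densities must be nonnegative")


@dataclass(frozen=True)
class ScoreRecord:
    """One unit's score under the Poisson mutational-target model."""

    unit_id: str
    n_obs: int
    lam: float
    p_raw: float
    p_corr: float
    rank: int


def genome_site_counts(ref_seq: str) -> tuple[int, int]:
    """(G/C site count, A/T site count) over the whole reference."""
    gc = ref_seq.count("G") + ref_seq.count("C")
    at = ref_seq.count("A") + ref_seq.count("T")
    return gc, at


def estimate_densities(
    mutations: Iterable[AnnotatedMutation],
    ref_seq: str,
    mode: str = "nonsynonymous",
) -> SiteDensities:
    """Estimate per-site mutation densities from the observed mutation set.

    ``mode='nonsynonymous'`` (default) feeds only mutations with at least
    one nonsynonymous CDS hit — the same class that is later scored, so
    the null model is self-consistent. ``mode='all'`` uses every filtered
    mutation.
    """
    if mode not in DENSITY_MODES:
        raise ValueError(f"mode must be one of {DENSITY_MODES}, got {mode!r}")
    gc_sites, at_sites = genome_site_counts(ref_seq)
    if gc_sites == 0 or at_sites == 0:
        raise ValueError("reference has zero G/C or zero A/T sites; cannot estimate densities")
    n_gc = n_at = 0
    for m in mutations:
        if mode == "nonsynonymous" and not m.is_nonsynonymous:
            continue
        if m.variant.ref in "GC":
            n_gc += 1
        else:
            n_at += 1
    n_used = n_gc + n_at
    if n_used == 0:
        log.warning("no mutations in class %r; densities are zero", mode)
    return SiteDensities(
        rho_gc=n_gc / gc_sites,
        rho_at=n_at / at_sites,
        n_mutations_used=n_used,
        mode=mode,
    )


def cross_section(unit: MutationTally, dens: SiteDensities) -> float:
    """Expected mutation count lambda of a unit from its site composition.

    Additive over genes: a group's cross-section is the sum of its member
    genes' cross-sections.
    """
    return unit.gc_sites * dens.rho_gc + unit.at_sites * dens.rho_at


def poisson_pvalue(n_obs: int, lam: float) -> float:
    """Upper-tail Poisson p-value P(X >= n_obs) for X ~ Poisson(lam).

    The tail includes the observed count, so n_obs = 0 gives p = 1.
    """
    if lam <= 0:
        raise ValueError(f"lam must be > 0, got {lam}")
    if n_obs < 0:
        raise ValueError(f"n_obs must be >= 0, got {n_obs}")
    return float(poisson.sf(n_obs - 1, lam))


def score_units(
    tallies: Sequence[MutationTally],
    dens: SiteDensities,
    n_tests: int,
) -> list[ScoreRecord]:
    """Score every unit and return records ranked by ascending raw p-value.

    Only nonsynonymous counts feed the observed count. ``n_tests`` is the
    Bonferroni correction factor and may exceed the number of scored units
    (e.g. correcting by the size of the whole group database rather than
    the number of groups hit). Ties are broken by descending observed
    count, then unit id, so output order is deterministic.
    """
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    records = []
    for t in tallies:
        lam = cross_section(t, dens)
        p = poisson_pvalue(t.ns, lam)
        records.append((p, -t.ns, t.unit_id, lam))
    records.sort()
    return [
        ScoreRecord(
            unit_id=unit_id,
            n_obs=-neg_ns,
            lam=lam,
            p_raw=p,
            p_corr=min(1.0, p * n_tests),
            rank=i + 1,
        )
        for i, (p, neg_ns, unit_id, lam) in enumerate(records)
    ]
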