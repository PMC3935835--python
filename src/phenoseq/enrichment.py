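"""Hypergeometric clustering of top-ranked genes within gene groups.

Given the top K genes of a gene-level ranking, asks whether they cluster
inside particular gene groups more than chance: for a group with
``group_size`` members inside the candidate universe, the probability that
a random draw of K genes from the universe contains at least the observed
number of members is the upper hypergeometric tail. Only groups that
intersect the top list are tested, and the Bonferroni factor is the number
of groups actually tested.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Collection, Iterable, Sequence

from scipy.stats import hypergeom

from .pathways import GeneGroup

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnrichmentResult:
    group_id: str
    k_in_top: int
    group_size: int
    K_top: int
    n_candidates: int
    p_raw: float
    p_corr: float
    rank: int


def enrich(
    top_genes: Sequence[str],
    groups: Iterable[GeneGroup],
    universe: Collection[str],
    restrict_to_universe: bool = True,
) -> list[EnrichmentResult]:
    """Hypergeometric enrichment of ``top_genes`` within each group.

    ``universe`` is the candidate gene pool the top list was drawn from
    (typically genes with at least one nonsynonymous mutation) and must
    contain the top list. With ``restrict_to_universe`` (default), a
    group's size is the number of members inside the universe — members
    that could never appear in the top list do not dilute the test.
    Groups not intersecting the top list are filtered out before the
    Bonferroni correction. Results are ranked by ascending raw p-value.
    """
    top = list(dict.fromkeys(top_genes))
    if not top:
        raise ValueError("top gene list is empty")
    universe_set = set(universe)
    missing = [g for g in top if g not in universe_set]
    if missing:
        raise ValueError(f"top genes not in universe: {missing[:5]}")
    top_set = set(top)
    K = len(top)
    N = len(universe_set)

    tested = []
    for grp in groups:
        members = grp.members & universe_set if restrict_to_universe else grp.members
        k = len(grp.members & top_set)
        if k == 0:
            continue
        size = len(members)
        p = float(hypergeom.sf(k - 1, N, size, K))
        tested.append((p, -k, grp.group_id, k, size))
    n_tests = len(tested)
    log.info("enrichment: %d of the supplied groups intersect the top-%d list", n_tests, K)
    tested.sort()
    return [
        EnrichmentResult(
            group_id=group_id,
            k_in_top=k,
            group_size=size,
            K_top=K,
            n_candidates=N,
            p_raw=p,
            p_corr=min(1.0, p * n_tests),
            rank=i + 1,
        )
        for i, (p, _negk, group_id, k, size) in enumerate(tested)
    ]
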