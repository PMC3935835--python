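"""Positive-selection evidence from nonsynonymous/synonymous count ratios.

Random mutagenesis is neutral: genome-wide, the nonsynonymous fraction of
mutations simply reflects codon structure. Phenotype screening, however,
enriches causal (necessarily nonsynonymous) mutations inside causal
pathways. This module tests that excess with a one-tailed ("greater")
Fisher exact test on the 2x2 table

    [[ns_in, syn_in], [ns_tot - ns_in, syn_tot - syn_in]],

per unit, cumulatively down a ranked pathway list, and with specified
genes excluded (to show the signal is not carried by a few genes already
significant on their own). No multiple-testing correction is applied to
the cumulative test: it is a single test on one nested family.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from scipy.stats import fisher_exact

from .pathways import GeneGroup, MutationTally

log = logging.getLogger(__name__)

CUMULATIVE_MODES = ("union", "per_group_sum")


@dataclass(frozen=True)
class SelectionResult:
    """One Fisher test on in-set vs genome-wide ns/syn counts.

    ``ka_ks_like`` is the in-set ns/syn count ratio normalized by the
    genome-wide ratio — a count-based analogue of Ka/Ks without codon
    opportunity normalization. It is ``inf`` when the set has
    nonsynonymous but no synonymous mutations, and ``nan`` for an empty
    set.
    """

    label: str
    ns_in: int
    syn_in: int
    ns_tot: int
    syn_tot: int
    p: float

    @property
    def ka_ks_like(self) -> float:
        if self.ns_in + self.syn_in == 0:
            return math.nan
        if self.syn_in == 0:
            return math.inf
        return (self.ns_in / self.syn_in) / (self.ns_tot / self.syn_tot)


def fisher_ns_syn(ns_in: int, syn_in: int, ns_tot: int, syn_tot: int) -> float:
    """One-tailed Fisher exact p-value for nonsynonymous excess.

    Equals the upper hypergeometric tail: the probability of drawing at
    least ``ns_in`` nonsynonymous mutations when ``ns_in + syn_in``
    mutations are sampled from the genome-wide pool of ``ns_tot``
    nonsynonymous plus ``syn_tot`` synonymous mutations. An empty set has
    p = 1.
    """
    for name, val in (("ns_in", ns_in), ("syn_in", syn_in), ("ns_tot", ns_tot), ("syn_tot", syn_tot)):
        if val < 0:
            raise ValueError(f"{name} must be nonnegative, got {val}")
    if ns_in > ns_tot or syn_in > syn_tot:
        raise ValueError(
            f"in-set counts ({ns_in}, {syn_in}) exceed totals ({ns_tot}, {syn_tot})"
        )
    if ns_in + syn_in == 0:
        return 1.0
    table = [[ns_in, syn_in], [ns_tot - ns_in, syn_tot - syn_in]]
    return float(fisher_exact(table, alternative="greater")[1])


def _pooled_counts(
    groups: Sequence[GeneGroup],
    gene_tallies: Mapping[str, MutationTally],
    mode: str,
    exclude: frozenset[str] = frozenset(),
) -> tuple[int, int]:
    """Pooled (ns, syn) over a list of groups.

    ``union`` counts each member gene once however many groups contain it
    (nested groups add nothing twice); ``per_group_sum`` adds group
    tallies, counting shared genes once per group.
    """
    if mode == "union":
        gene_ids = {m for grp in groups for m in grp.members} - exclude
        ns = sum(gene_tallies[g].ns for g in gene_ids if g in gene_tallies)
        syn = sum(gene_tallies[g].syn for g in gene_ids if g in gene_tallies)
    elif mode == "per_group_sum":
        ns = syn = 0
        for grp in groups:
            for g in grp.members - exclude:
                if g in gene_tallies:
                    ns += gene_tallies[g].ns
                    syn += gene_tallies[g].syn
    else:
        raise ValueError(f"mode must be one of {CUMULATIVE_MODES}, got {mode!r}")
    return ns, syn


def cumulative_selection(
    ranked_groups: Sequence[GeneGroup],
    gene_tallies: Mapping[str, MutationTally],
    ns_tot: int,
    syn_tot: int,
    mode: str = "union",
) -> list[SelectionResult]:
    """Fisher tests on the pooled counts of the top 1..k ranked groups.

    Result k tests groups 1..k together; a prefix of one group is exactly
    the single-group test. Default pooling is union-of-genes.
    """
    out: list[SelectionResult] = []
    for k in range(1, len(ranked_groups) + 1):
        ns, syn = _pooled_counts(ranked_groups[:k], gene_tallies, mode)
        out.append(
            SelectionResult(
                label=f"top{k}:{ranked_groups[k - 1].group_id}",
                ns_in=ns,
                syn_in=syn,
                ns_tot=ns_tot,
                syn_tot=syn_tot,
                p=fisher_ns_syn(ns, syn, ns_tot, syn_tot),
            )
        )
    return out


def selection_excluding(
    groups: Sequence[GeneGroup],
    excluded_genes: Iterable[str],
    gene_tallies: Mapping[str, MutationTally],
    ns_tot: int,
    syn_tot: int,
    mode: str = "union",
) -> SelectionResult:
    """Pooled Fisher test with the named genes' mutations dropped.

    Genome-wide totals are unchanged; gene-name matching is
    case-insensitive, and an excluded name matching no member is ignored
    with a warning.
    """
    member_by_lower = {m.lower(): m for grp in groups for m in grp.members}
    exclude = set()
    for name in excluded_genes:
        hit = member_by_lower.get(name.lower())
        if hit is None:
            log.warning("excluded gene %r not found in any group; ignored", name)
        else:
            exclude.add(hit)
    ns, syn = _pooled_counts(groups, gene_tallies, mode, exclude=frozenset(exclude))
    label = "all" if not exclude else "excluding " + ",".join(sorted(exclude))
    return SelectionResult(
        label=label,
        ns_in=ns,
        syn_in=syn,
        ns_tot=ns_tot,
        syn_tot=syn_tot,
        p=fisher_ns_syn(ns, syn, ns_tot, syn_tot),
    )
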