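"""Gene-group (pathway) definitions and per-unit mutation tallies.

A "pathway" here is any named set of genes acting together — an EcoCyc
functionally associated group, a complex, an operon — read from a flat TSV
file (``group_id<TAB>gene1 gene2 ...``). Tallies count nonsynonymous and
synonymous hits per gene and, additively over member genes, per group; a
mutation altering two member genes of one group therefore counts once per
gene. Site composition (GC/AT) is carried alongside so the scoring module
can compute each unit's mutational cross-section.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .annotation import NONSYNONYMOUS, SYNONYMOUS, AnnotatedMutation, GeneModel

log = logging.getLogger(__name__)

_MEMBER_SPLIT = re.compile(r"[,\s]+")


@dataclass(frozen=True)
class GeneGroup:
    """A named, nonempty set of member gene names."""

    group_id: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"group {self.group_id} has no members")


@dataclass(frozen=True)
class MutationTally:
    """Per-unit (gene or group) mutation counts and site composition."""

    unit_id: str
    ns: int
    syn: int
    gc_sites: int
    at_sites: int

    def __post_init__(self) -> None:
        if self.ns < 0 or self.syn < 0:
            raise ValueError("negative mutation count")

    @property
    def n_total(self) -> int:
        return self.ns + self.syn


def load_groups(path) -> list[GeneGroup]:
    """Read group definitions from TSV: group id, tab, member gene names.

    Member names may be separated by commas or whitespace. Duplicate group
    ids and empty member lists are errors (with the offending line number).
    Lines that are blank or start with ``#`` are ignored.
    """
    groups: list[GeneGroup] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t", 1)
            if len(fields) != 2:
                raise ValueError(f"{path}:{lineno}: expected 'group<TAB>members'")
            group_id = fields[0].strip()
            members = frozenset(m for m in _MEMBER_SPLIT.split(fields[1].strip()) if m)
            if not group_id or not members:
                raise ValueError(f"{path}:{lineno}: empty group id or member list")
            if group_id in seen:
                raise ValueError(f"{path}:{lineno}: duplicate group id {group_id!r}")
            seen.add(group_id)
            groups.append(GeneGroup(group_id=group_id, members=members))
    log.info("loaded %d gene groups from %s", len(groups), path)
    return groups


def resolve_groups(
    groups: Iterable[GeneGroup],
    genes: Sequence[GeneModel],
) -> list[GeneGroup]:
    """Map member names onto loaded gene models.

    Matching is case-insensitive on locus tag or gene symbol (first match
    wins, in gene order); unresolved members are dropped with a warning,
    and a group whose members all fail to resolve is dropped entirely.
    """
    lookup: dict[str, str] = {}
    for g in genes:
        for name in (g.gene_id, g.gene_symbol, g.locus_tag):
            if name and name.lower() not in lookup:
                lookup[name.lower()] = g.gene_id
    resolved: list[GeneGroup] = []
    n_dropped_members = 0
    for grp in groups:
        members = []
        for m in grp.members:
            hit = lookup.get(m.lower())
            if hit is None:
                n_dropped_members += 1
                log.warning("group %s: member %r not in genome annotation; dropped", grp.group_id, m)
            else:
                members.append(hit)
        if members:
            resolved.append(GeneGroup(group_id=grp.group_id, members=frozenset(members)))
        else:
            log.warning("group %s: no members resolved; group dropped", grp.group_id)
    if n_dropped_members:
        log.info("dropped %d unresolved member name(s)", n_dropped_members)
    return resolved


def tally_genes(
    annotated: Iterable[AnnotatedMutation],
    genes: Sequence[GeneModel],
) -> dict[str, MutationTally]:
    """Nonsynonymous/synonymous hit counts for every gene (zero-filled)."""
    ns: dict[str, int] = {g.gene_id: 0 for g in genes}
    syn: dict[str, int] = {g.gene_id: 0 for g in genes}
    for ann in annotated:
        for gene_id, _codon, effect in ann.hits:
            if gene_id not in ns:
                continue
            if effect == NONSYNONYMOUS:
                ns[gene_id] += 1
            elif effect == SYNONYMOUS:
                syn[gene_id] += 1
    return {
        g.gene_id: MutationTally(
            unit_id=g.gene_id,
            ns=ns[g.gene_id],
            syn=syn[g.gene_id],
            gc_sites=g.gc_sites,
            at_sites=g.at_sites,
        )
        for g in genes
    }


def tally_groups(
    gene_tallies: Mapping[str, MutationTally],
    groups: Iterable[GeneGroup],
) -> list[MutationTally]:
    """Group tallies as sums over member genes (counts and composition)."""
    out: list[MutationTally] = []
    for grp in groups:
        members = [gene_tallies[m] for m in sorted(grp.members) if m in gene_tallies]
        out.append(
            MutationTally(
                unit_id=grp.group_id,
                ns=sum(t.ns for t in members),
                syn=sum(t.syn for t in members),
                gc_sites=sum(t.gc_sites for t in members),
                at_sites=sum(t.at_sites for t in members),
            )
        )
    return out


def tally(
    annotated: Iterable[AnnotatedMutation],
    genes: Sequence[GeneModel],
    groups: Iterable[GeneGroup] | None = None,
) -> list[MutationTally]:
    """Tally per gene, or per group when ``groups`` is given."""
    per_gene = tally_genes(annotated, genes)
    if groups is None:
        return list(per_gene.values())
    return tally_groups(per_gene, groups)
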