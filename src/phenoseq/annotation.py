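"""Mapping SNPs onto CDS features and calling synonymous/nonsynonymous effects.

Loads an annotated reference genome from a GenBank flat file, builds one
:class:`GeneModel` per CDS feature (strand-corrected coding sequence plus
the GC/AT site composition of the gene's genomic span, which later feeds
the mutational cross-section), and classifies each filtered SNP by whether
the codon change alters the amino acid under the bacterial genetic code
(translation table 11 by default). Mutations creating stop codons count as
nonsynonymous. A SNP overlapping several CDSs yields one hit per CDS.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from functools import lru_cache

from Bio import SeqIO
from Bio.Data import CodonTable
from intervaltree import IntervalTree

from .variants import VariantCall

log = logging.getLogger(__name__)

SYNONYMOUS = "synonymous"
NONSYNONYMOUS = "nonsynonymous"

_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}


@lru_cache(maxsize=None)
def _codon_map(table: int) -> dict[str, str]:
    ct = CodonTable.unambiguous_dna_by_id[table]
    mapping = dict(ct.forward_table)
    for stop in ct.stop_codons:
        mapping[stop] = "*"
    return mapping


def translate_codon(codon: str, table: int = 11) -> str:
    """Amino acid (or ``*`` for stop) of one codon under ``table``."""
    return _codon_map(table)[codon.upper()]


@dataclass(frozen=True)
class GeneModel:
    """One CDS with strand-corrected coding sequence and site composition.

    ``cds_intervals`` are 0-based half-open genomic intervals in genomic
    order; ``coding_sequence`` reads 5'→3' on the coding strand.
    ``gc_sites``/``at_sites`` count G/C and A/T positions over the gene's
    genomic span (strand-independent).
    """

    gene_id: str
    strand: int
    cds_intervals: tuple[tuple[int, int], ...]
    coding_sequence: str
    gc_sites: int
    at_sites: int
    locus_tag: str | None = None
    gene_symbol: str | None = None

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.cds_intervals)

    def contains(self, pos0: int) -> bool:
        return any(s <= pos0 < e for s, e in self.cds_intervals)

    def coding_offset(self, pos0: int) -> int:
        """Offset of genomic position ``pos0`` within the coding sequence."""
        fwd = 0
        for s, e in self.cds_intervals:
            if s <= pos0 < e:
                fwd += pos0 - s
                break
            fwd += e - s
        else:
            raise ValueError(f"position {pos0} not in CDS of {self.gene_id}")
        return fwd if self.strand > 0 else self.length - 1 - fwd


@dataclass(frozen=True)
class AnnotatedMutation:
    """A filtered SNP with its per-CDS effect calls.

    ``hits`` holds ``(gene_id, codon_index, effect)`` triples, one per CDS
    the SNP falls in; an empty tuple marks a non-coding position.
    """

    variant: VariantCall
    hits: tuple[tuple[str, int, str], ...]

    @property
    def noncoding(self) -> bool:
        return not self.hits

    @property
    def is_nonsynonymous(self) -> bool:
        return any(effect == NONSYNONYMOUS for _, _, effect in self.hits)

    @property
    def is_synonymous(self) -> bool:
        return bool(self.hits) and all(
            effect == SYNONYMOUS for _, _, effect in self.hits
        )


def load_genome(path) -> tuple[str, list[GeneModel]]:
    """Read a GenBank file into (reference sequence, gene models).

    One :class:`GeneModel` per CDS feature; overlapping CDSs are allowed.
    CDSs whose total length is not a multiple of 3 (pseudogene artifacts,
    truncated annotations) are logged and excluded from effect calling.
    A file without sequence is a fatal error.
    """
    record = SeqIO.read(str(path), "genbank")
    try:
        ref_seq = str(record.seq).upper()
    except Exception as exc:  # Bio.Seq.UndefinedSequenceError and friends
        raise ValueError(f"GenBank file {path} has no sequence: {exc}") from exc
    if not ref_seq:
        raise ValueError(f"GenBank file {path} has no sequence")

    genes: list[GeneModel] = []
    n_skipped = 0
    for i, feat in enumerate(f for f in record.features if f.type == "CDS"):
        strand = feat.location.strand
        if strand not in (1, -1):
            log.warning("CDS #%d has no defined strand; skipped", i)
            n_skipped += 1
            continue
        parts = sorted(feat.location.parts, key=lambda p: int(p.start))
        intervals = tuple((int(p.start), int(p.end)) for p in parts)
        length = sum(e - s for s, e in intervals)
        symbol = feat.qualifiers.get("gene", [None])[0]
        locus = feat.qualifiers.get("locus_tag", [None])[0]
        gene_id = symbol or locus or f"cds_{i}"
        if length % 3 != 0:
            log.warning(
                "CDS %s has length %d (not a codon multiple); excluded from effect calling",
                gene_id, length,
            )
            n_skipped += 1
            continue
        coding = str(feat.extract(record.seq)).upper()
        span = "".join(ref_seq[s:e] for s, e in intervals)
        gc = sum(1 for b in span if b in "GC")
        genes.append(
            GeneModel(
                gene_id=gene_id,
                strand=int(strand),
                cds_intervals=intervals,
                coding_sequence=coding,
                gc_sites=gc,
                at_sites=length - gc,
                locus_tag=locus,
                gene_symbol=symbol,
            )
        )
    log.info("loaded %d CDS models (%d skipped) from %s", len(genes), n_skipped, path)
    return ref_seq, genes


def classify_effect(
    variant: VariantCall,
    gene: GeneModel,
    ref_seq: str,
    table: int = 11,
) -> tuple[str, int]:
    """Classify a SNP inside ``gene`` as synonymous or nonsynonymous.

    Returns ``(effect, codon_index)``. Reverse-strand genes complement
    ref/alt before substituting into the codon. A mismatch between the
    variant's ref base and the reference sequence signals the wrong
    reference genome and raises ``ValueError`` naming the position.
    """
    pos0 = variant.pos - 1
    if not gene.contains(pos0):
        raise ValueError(f"variant at {variant.chrom}:{variant.pos} not in {gene.gene_id}")
    if ref_seq[pos0] != variant.ref:
        raise ValueError(
            f"reference mismatch at {variant.chrom}:{variant.pos}: "
            f"VCF ref {variant.ref!r} but genome has {ref_seq[pos0]!r}"
        )
    offset = gene.coding_offset(pos0)
    if gene.strand > 0:
        ref_c, alt_c = variant.ref, variant.alt
    else:
        ref_c, alt_c = _COMPLEMENT[variant.ref], _COMPLEMENT[variant.alt]
    codon_index = offset // 3
    within = offset % 3
    codon = gene.coding_sequence[3 * codon_index : 3 * codon_index + 3]
    if codon[within] != ref_c:
        raise ValueError(
            f"internal inconsistency: coding base {codon[within]!r} != ref {ref_c!r} "
            f"for {gene.gene_id} at {variant.chrom}:{variant.pos}"
        )
    mutated = codon[:within] + alt_c + codon[within + 1 :]
    aa_ref = translate_codon(codon, table)
    aa_alt = translate_codon(mutated, table)
    return (SYNONYMOUS if aa_ref == aa_alt else NONSYNONYMOUS), codon_index


def build_gene_index(genes: Iterable[GeneModel]) -> IntervalTree:
    """Interval tree over CDS intervals for O(log n + k) point queries."""
    tree = IntervalTree()
    for gene in genes:
        for s, e in gene.cds_intervals:
            tree.addi(s, e, gene)
    return tree


def annotate_all(
    kept: Sequence[VariantCall],
    genes: Sequence[GeneModel],
    ref_seq: str,
    table: int = 11,
    index: IntervalTree | None = None,
) -> list[AnnotatedMutation]:
    """Annotate every filtered SNP against every CDS it falls in."""
    tree = index if index is not None else build_gene_index(genes)
    out: list[AnnotatedMutation] = []
    for v in kept:
        pos0 = v.pos - 1
        overlapping = sorted(
            {iv.data for iv in tree.at(pos0)}, key=lambda g: g.gene_id
        )
        hits = tuple(
            (g.gene_id, *_swap(classify_effect(v, g, ref_seq, table=table)))
            for g in overlapping
        )
        out.append(AnnotatedMutation(variant=v, hits=hits))
    return out


def _swap(effect_and_index: tuple[str, int]) -> tuple[int, str]:
    effect, codon_index = effect_and_index
    return codon_index, effect
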