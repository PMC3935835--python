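"""Plain-text I/O helpers: VCF writing and TSV round-trips.

Everything the pipeline exchanges between stages is diffable text: VCF for
variant calls (read back with pysam), TSV for variants, annotated
mutations, tallies and score tables (via pandas).
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam

from .annotation import AnnotatedMutation
from .variants import VariantCall

_VCF_INFO_LINES = (
    '##INFO=<ID=AF1,Number=1,Type=Float,Description='
    '"Max-likelihood estimate of the first ALT allele frequency">',
    '##INFO=<ID=PV4,Number=4,Type=Float,Description='
    '"P-values for strand bias, baseQ bias, mapQ bias and tail distance bias">',
)


def write_vcf(path, contig_lengths: Mapping[str, int], rows: Iterable[tuple]) -> None:
    """Write VCF records given as (chrom, pos1, ref, alts, qual, info) tuples.

    ``alts`` is a tuple of alternate alleles (so indel and multi-allelic
    test records can be produced); ``info`` maps INFO keys (AF1, PV4) to
    values. Records are written in the order given.
    """
    header = pysam.VariantHeader()
    header.add_line("##source=phenoseq")
    for line in _VCF_INFO_LINES:
        header.add_line(line)
    for name, length in contig_lengths.items():
        header.contigs.add(name, length=length)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for chrom, pos1, ref, alts, qual, info in rows:
            rec = out.new_record(
                contig=chrom,
                start=pos1 - 1,
                stop=pos1 - 1 + len(ref),
                alleles=(ref, *alts),
                qual=qual,
            )
            for key, val in info.items():
                rec.info[key] = val
            out.write(rec)


def write_pool_vcf(
    calls: Sequence[VariantCall],
    path,
    contig_lengths: Mapping[str, int],
) -> None:
    """Write one pool's SNP calls as a sorted single-sample-free VCF."""
    rows = []
    for c in sorted(calls, key=lambda c: (c.chrom, c.pos, c.alt)):
        info: dict = {}
        if c.allele_freq is not None:
            info["AF1"] = c.allele_freq
        if c.strand_bias_p is not None:
            info["PV4"] = (c.strand_bias_p, 1.0, 1.0, 1.0)
        rows.append((c.chrom, c.pos, c.ref, (c.alt,), c.qual, info))
    write_vcf(path, contig_lengths, rows)


_VARIANT_COLS = ["chrom", "pos", "ref", "alt", "qual", "pool_id", "allele_freq", "strand_bias_p"]


def variants_to_tsv(calls: Iterable[VariantCall], path) -> None:
    df = pd.DataFrame(
        [
            (c.chrom, c.pos, c.ref, c.alt, c.qual, c.pool_id, c.allele_freq, c.strand_bias_p)
            for c in calls
        ],
        columns=_VARIANT_COLS,
    )
    df.to_csv(path, sep="\t", index=False)


def variants_from_tsv(path) -> list[VariantCall]:
    df = pd.read_csv(path, sep="\t")
    calls = []
    for row in df.itertuples(index=False):
        calls.append(
            VariantCall(
                chrom=row.chrom,
                pos=int(row.pos),
                ref=row.ref,
                alt=row.alt,
                qual=float(row.qual),
                pool_id=str(row.pool_id),
                allele_freq=None if _isnan(row.allele_freq) else float(row.allele_freq),
                strand_bias_p=None if _isnan(row.strand_bias_p) else float(row.strand_bias_p),
            )
        )
    return calls


def _isnan(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


def annotated_to_tsv(annotated: Iterable[AnnotatedMutation], path) -> None:
    """One row per (variant, CDS hit); non-coding variants get one row
    with empty gene/effect fields."""
    rows = []
    for ann in annotated:
        v = ann.variant
        base = (v.chrom, v.pos, v.ref, v.alt, v.qual, v.pool_id, v.allele_freq, v.strand_bias_p)
        if ann.hits:
            for gene_id, codon_index, effect in ann.hits:
                rows.append((*base, gene_id, codon_index, effect))
        else:
            rows.append((*base, None, None, None))
    df = pd.DataFrame(rows, columns=_VARIANT_COLS + ["gene", "codon_index", "effect"])
    df.to_csv(path, sep="\t", index=False)


def annotated_from_tsv(path) -> list[AnnotatedMutation]:
    df = pd.read_csv(path, sep="\t")
    grouped: dict[tuple, tuple[VariantCall, list]] = {}
    for row in df.itertuples(index=False):
        key = (row.chrom, int(row.pos), row.ref, row.alt, str(row.pool_id))
        if key not in grouped:
            v = VariantCall(
                chrom=row.chrom,
                pos=int(row.pos),
                ref=row.ref,
                alt=row.alt,
                qual=float(row.qual),
                pool_id=str(row.pool_id),
                allele_freq=None if _isnan(row.allele_freq) else float(row.allele_freq),
                strand_bias_p=None if _isnan(row.strand_bias_p) else float(row.strand_bias_p),
            )
            grouped[key] = (v, [])
        if not _isnan(row.gene) and isinstance(row.gene, str):
            grouped[key][1].append((row.gene, int(row.codon_index), row.effect))
    return [AnnotatedMutation(variant=v, hits=tuple(hits)) for v, hits in grouped.values()]


def records_to_tsv(records: Iterable, path, columns: Sequence[str]) -> None:
    """Write any iterable of (data)class records to TSV by attribute name."""
    df = pd.DataFrame([[getattr(r, c) for c in columns] for r in records], columns=list(columns))
    df.to_csv(path, sep="\t", index=False)
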