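"""CDS mapping and synonymous/nonsynonymous effect calling."""

from __future__ import annotations

import pytest
from Bio.Seq import Seq

from phenoseq.annotation import (
    NONSYNONYMOUS,
    SYNONYMOUS,
    AnnotatedMutation,
    GeneModel,
    annotate_all,
    classify_effect,
    load_genome,
)

from conftest import TOY_FWD_IV, TOY_REV_IV, TOY_SEQ, make_call


def _gene(genes, gene_id):
    return next(g for g in genes if g.gene_id == gene_id)


class TestLoadGenome:
    def test_models_and_strand_corrected_coding(self, toy_genome):
        ref_seq, genes = toy_genome
        assert ref_seq == TOY_SEQ
        assert sorted(g.gene_id for g in genes) == ["fwdA", "revB"]
        fwd, rev = _gene(genes, "fwdA"), _gene(genes, "revB")
        assert fwd.strand == 1 and rev.strand == -1
        assert fwd.coding_sequence == "ATGGATCTGTAA"
        assert rev.coding_sequence == "ATGGATTGA"
        assert fwd.cds_intervals == (TOY_FWD_IV,)
        assert rev.cds_intervals == (TOY_REV_IV,)

    def test_non_triplet_cds_excluded(self, toy_genome):
        # the toy file carries a 10 bp CDS (brokenC): not a codon multiple
        _, genes = toy_genome
        assert "brokenC" not in {g.gene_id for g in genes}

    def test_site_composition(self, toy_genome):
        ref_seq, genes = toy_genome
        for g in genes:
            span = "".join(ref_seq[s:e] for s, e in g.cds_intervals)
            assert g.gc_sites == sum(1 for b in span if b in "GC")
            assert g.gc_sites + g.at_sites == g.length

    def test_all_gc_gene_has_zero_at_sites(self):
        g = GeneModel("x", 1, ((0, 6),), "GGGCCC", gc_sites=6, at_sites=0)
        assert g.at_sites == 0 and g.gc_sites == g.length


class TestClassifyEffect:
    def test_forward_third_position_nonsynonymous(self, toy_genome):
        """GAT -> GAA (Asp -> Glu)."""
        ref_seq, genes = toy_genome
        v = make_call(TOY_FWD_IV[0] + 5 + 1, ref="T", alt="A")
        effect, codon_i = classify_effect(v, _gene(genes, "fwdA"), ref_seq)
        assert (effect, codon_i) == (NONSYNONYMOUS, 1)

    def test_forward_synonymous(self, toy_genome):
        """CTG -> CTA (Leu -> Leu)."""
        ref_seq, genes = toy_genome
        v = make_call(TOY_FWD_IV[0] + 8 + 1, ref="G", alt="A")
        effect, codon_i = classify_effect(v, _gene(genes, "fwdA"), ref_seq)
        assert (effect, codon_i) == (SYNONYMOUS, 2)

    def test_reverse_strand_complemented(self, toy_genome):
        """Genomic C->T hits coding GAT as G->A: GAT -> AAT (Asp -> Asn)."""
        ref_seq, genes = toy_genome
        rev = _gene(genes, "revB")
        # coding offset 3 ('G' of codon 2) maps to genomic start + L-1-3
        pos0 = TOY_REV_IV[0] + (rev.length - 1 - 3)
        assert ref_seq[pos0] == "C"
        v = make_call(pos0 + 1, ref="C", alt="T")
        effect, codon_i = classify_effect(v, rev, ref_seq)
        assert (effect, codon_i) == (NONSYNONYMOUS, 1)

    def test_stop_creation_is_nonsynonymous(self, toy_genome):
        """TGG-like change creating a stop counts as nonsynonymous; here
        CTG -> taG via T->G at codon 3 position 3? use GAT -> TAT then
        TAA stop context: mutate fwdA codon 2 GAT first base G->T (Asp->Tyr)."""
        ref_seq, genes = toy_genome
        v = make_call(TOY_FWD_IV[0] + 3 + 1, ref="G", alt="T")
        effect, _ = classify_effect(v, _gene(genes, "fwdA"), ref_seq)
        assert effect == NONSYNONYMOUS

    def test_ref_mismatch_raises_with_position(self, toy_genome):
        ref_seq, genes = toy_genome
        pos = TOY_FWD_IV[0] + 1  # genome has 'A' here (ATG start)
        v = make_call(pos, ref="C", alt="T")
        with pytest.raises(ValueError, match=str(pos)):
            classify_effect(v, _gene(genes, "fwdA"), ref_seq)


class TestAnnotateAll:
    def test_intergenic_is_noncoding(self, toy_genome):
        ref_seq, genes = toy_genome
        (ann,) = annotate_all([make_call(1, ref="A", alt="G")], genes, ref_seq)
        assert ann.noncoding and ann.hits == ()

    def test_overlapping_cds_yields_two_hits(self):
        seq = "ATGGATCTGTAAATTT"
        g1 = GeneModel("ovlA", 1, ((0, 12),), seq[0:12], 5, 7)
        g2 = GeneModel("ovlB", 1, ((3, 15),), seq[3:15], 5, 7)
        v = make_call(7, ref=seq[6], alt="A", chrom="c")
        (ann,) = annotate_all([v], [g1, g2], seq)
        assert {h[0] for h in ann.hits} == {"ovlA", "ovlB"}

    def test_mixed_fixture_counts(self, toy_genome):
        ref_seq, genes = toy_genome
        calls = [
            make_call(1, ref="A", alt="G"),                  # intergenic
            make_call(TOY_FWD_IV[0] + 6, ref="T", alt="A"),  # fwdA
            make_call(TOY_FWD_IV[0] + 9, ref="G", alt="A"),  # fwdA
            make_call(TOY_REV_IV[0] + 1, ref=ref_seq[TOY_REV_IV[0]],
                      alt="G" if ref_seq[TOY_REV_IV[0]] != "G" else "A"),  # revB
            make_call(25, ref=ref_seq[24], alt="G" if ref_seq[24] != "G" else "A"),
        ]
        anns = annotate_all(calls, genes, ref_seq)
        assert sum(1 for a in anns if a.hits) == 3


def _brute_force_effect(gene: GeneModel, offset: int, alt_coding: str) -> str:
    """Oracle: mutate the whole coding sequence and translate everything."""
    coding = gene.coding_sequence
    mutated = coding[:offset] + alt_coding + coding[offset + 1 :]
    before = str(Seq(coding).translate(table=11))
    after = str(Seq(mutated).translate(table=11))
    return SYNONYMOUS if before == after else NONSYNONYMOUS


def test_all_point_mutations_match_translate_everything_oracle(toy_genome):
    """classify_effect partitions all 3L possible substitutions of each gene
    exactly as full-protein re-translation does."""
    ref_seq, genes = toy_genome
    comp = {"A": "T", "T": "A", "G": "C", "C": "G"}
    for gene in genes:
        (s, e), = gene.cds_intervals
        for pos0 in range(s, e):
            ref = ref_seq[pos0]
            for alt in "ACGT":
                if alt == ref:
                    continue
                v = make_call(pos0 + 1, ref=ref, alt=alt)
                effect, _ = classify_effect(v, gene, ref_seq)
                offset = gene.coding_offset(pos0)
                alt_coding = alt if gene.strand > 0 else comp[alt]
                assert effect == _brute_force_effect(gene, offset, alt_coding), (
                    gene.gene_id, pos0, ref, alt)


def test_strand_round_trip():
    """A gene and its reverse-complemented twin on the opposite strand make
    identical effect calls for corresponding mutations."""
    coding = "ATGGATCTGACCTGGTAA"
    L = len(coding)
    fwd_seq = coding
    rev_seq = str(Seq(coding).reverse_complement())
    gc = sum(1 for b in coding if b in "GC")
    fwd = GeneModel("f", 1, ((0, L),), coding, gc, L - gc)
    rev = GeneModel("r", -1, ((0, L),), coding, gc, L - gc)
    comp = {"A": "T", "T": "A", "G": "C", "C": "G"}
    for offset in range(L):
        ref_f = fwd_seq[offset]
        for alt in "ACGT":
            if alt == ref_f:
                continue
            ef, ci_f = classify_effect(make_call(offset + 1, ref=ref_f, alt=alt), fwd, fwd_seq)
            # same coding-strand mutation on the twin: genomic pos L-1-offset
            pos0_r = L - 1 - offset
            er, ci_r = classify_effect(
                make_call(pos0_r + 1, ref=comp[ref_f], alt=comp[alt]), rev, rev_seq)
            assert (ef, ci_f) == (er, ci_r)


def test_annotated_mutation_effect_flags():
    v = make_call(1)
    both = AnnotatedMutation(v, (("a", 0, NONSYNONYMOUS), ("b", 0, SYNONYMOUS)))
    assert both.is_nonsynonymous and not both.is_synonymous
    syn = AnnotatedMutation(v, (("a", 0, SYNONYMOUS),))
    assert syn.is_synonymous and not syn.is_nonsynonymous
    assert AnnotatedMutation(v, ()).noncoding
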