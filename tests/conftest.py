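"""Shared fixtures: a hand-built toy GenBank genome and VariantCall factory.

The toy genome (45+ bp) carries one forward-strand CDS (ATG GAT CTG TAA),
one reverse-strand CDS (coding ATG GAT TGA stored as its genomic reverse
complement) and one deliberately broken CDS of length 10, so annotation
tests can check strand handling and pseudogene exclusion against
hand-translated expectations.
"""

from __future__ import annotations

import pytest
from Bio.Seq import Seq
from Bio.SeqFeature import SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO
from hypothesis import settings

from phenoseq.variants import VariantCall

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")

# layout: spacer[0:10) + fwd CDS[10:22) + spacer[22:30) + rev CDS[30:39)
#         + spacer/pseudo region [39:51), pseudo CDS [39:49) (length 10)
TOY_FWD_CODING = "ATGGATCTGTAA"  # M D L *
TOY_REV_CODING = "ATGGATTGA"  # M D *
TOY_SEQ = (
    "AATTCCGGAA"
    + TOY_FWD_CODING
    + "ACGTACGT"
    + str(Seq(TOY_REV_CODING).reverse_complement())
    + "AAATTTGGGCCC"
)
TOY_FWD_IV = (10, 22)
TOY_REV_IV = (30, 39)


@pytest.fixture(scope="session")
def toy_genbank(tmp_path_factory):
    """Path to the toy GenBank file (written once per session)."""
    rec = SeqRecord(Seq(TOY_SEQ), id="toychr", name="toychr", description="toy")
    rec.annotations["molecule_type"] = "DNA"
    rec.features = [
        SeqFeature(SimpleLocation(*TOY_FWD_IV, strand=1), type="CDS",
                   qualifiers={"gene": ["fwdA"], "locus_tag": ["TOY0001"]}),
        SeqFeature(SimpleLocation(*TOY_REV_IV, strand=-1), type="CDS",
                   qualifiers={"gene": ["revB"], "locus_tag": ["TOY0002"]}),
        SeqFeature(SimpleLocation(39, 49, strand=1), type="CDS",
                   qualifiers={"gene": ["brokenC"], "locus_tag": ["TOY0003"]}),
    ]
    path = tmp_path_factory.mktemp("toy") / "toy.gb"
    SeqIO.write(rec, str(path), "genbank")
    return path


@pytest.fixture(scope="session")
def toy_genome(toy_genbank):
    """(ref_seq, genes) loaded from the toy GenBank file."""
    from phenoseq.annotation import load_genome

    return load_genome(toy_genbank)


def make_call(
    pos: int,
    ref: str = "A",
    alt: str = "G",
    *,
    chrom: str = "toychr",
    qual: float = 150.0,
    pool_id: str = "pool1",
    allele_freq: float | None = 0.33,
    strand_bias_p: float | None = 0.5,
) -> VariantCall:
    """VariantCall with passing-by-default filter fields."""
    return VariantCall(
        chrom=chrom, pos=pos, ref=ref, alt=alt, qual=qual, pool_id=pool_id,
        allele_freq=allele_freq, strand_bias_p=strand_bias_p,
    )


@pytest.fixture
def small_bundle():
    """A small synthetic experiment with one implanted 2-gene causal group."""
    from phenoseq.synth import CausalGroupSpec, SyntheticConfig, generate

    cfg = SyntheticConfig(
        n_genes=60, n_groups=40, n_strains=6, pool_size=3, n_pools=2,
        mutations_per_strain=30, causal_groups=(CausalGroupSpec(),), seed=7,
    )
    return generate(cfg)
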