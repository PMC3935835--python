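"""Synthetic phenotype-sequencing experiments with known ground truth.

Emulates the study design the package analyzes: two dozen independently
NTG-mutagenized bacterial strains (~100 point mutations each, heavily
biased to G/C sites), screened for a phenotype whose genetic cause is
implanted as one or more "causal" gene groups that every strain must hit
nonsynonymously, then pooled three strains per tagged library and
sequenced. The generator produces a random annotated genome (GenBank), a
gene-group database (TSV), per-pool variant calls (VCF), and a
:class:`TruthSet` recording every implanted mutation — so the entire
pipeline can be exercised and validated without any external data.

Background mutation sites are sampled without replacement across strains
(independent mutants essentially never hit the same base twice), so every
true mutation appears in exactly one pool at carrier fraction 1/pool_size.
Optional artifact injection adds calls that violate exactly one filter
each — low quality, strand bias, high allele frequency, or presence in
every pool (parental) — to exercise the filter cascade's bookkeeping.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .annotation import NONSYNONYMOUS, SYNONYMOUS, GeneModel, translate_codon
from .io import write_pool_vcf
from .pathways import GeneGroup
from .variants import VariantCall

log = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {
    "A": ("C", "T"), "G": ("C", "T"), "C": ("A", "G"), "T": ("A", "G"),
}
_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}

CONTIG = "synchr"


@dataclass(frozen=True)
class CausalGroupSpec:
    """An implanted causal gene group.

    With ``per_strain_prob=None`` every strain receives exactly
    ``hits_per_strain`` nonsynonymous mutations in the group (the
    "every screened mutant carries a causal hit" design); otherwise each
    strain is hit once with that probability.
    """

    n_genes: int = 2
    hits_per_strain: int = 1
    per_strain_prob: float | None = None


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic experiment.

    Defaults mirror the emulated design: 24 strains at ~100 mutations
    each with 95% of mutations on G/C sites (NTG-like, mostly
    transitions), pooled 3 per library into 8 pools; a 500-gene genome
    and a 536-group pathway database.
    """

    n_genes: int = 500
    gene_length_range: tuple[int, int] = (300, 1500)  # bp, rounded to codons
    intergenic_length: int = 20
    gc_content: float = 0.5
    n_groups: int = 536
    group_size_range: tuple[int, int] = (2, 12)
    n_strains: int = 24
    mutations_per_strain: int = 100
    gc_mutation_bias: float = 0.95
    transition_bias: float = 0.9
    causal_groups: tuple[CausalGroupSpec, ...] = ()
    pool_size: int = 3
    n_pools: int = 8
    af_jitter_sd: float = 0.03
    qual_range: tuple[float, float] = (120.0, 220.0)
    n_low_qual: int = 0
    n_high_af: int = 0
    n_strand_bias: int = 0
    n_parental: int = 0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.pool_size * self.n_pools != self.n_strains:
            raise ValueError("pool_size * n_pools must equal n_strains")
        if not 0.0 <= self.gc_mutation_bias <= 1.0:
            raise ValueError("gc_mutation_bias must be in [0, 1]")
        if not 0.0 < self.gc_content < 1.0:
            raise ValueError("gc_content must be in (0, 1)")


@dataclass(frozen=True)
class TrueMutation:
    strain: int
    pos: int  # 1-based
    ref: str
    alt: str
    gene_id: str | None
    effect: str | None
    causal_group: str | None


@dataclass
class TruthSet:
    """Generator bookkeeping: what was implanted, where."""

    strain_mutations: list[list[TrueMutation]]
    gene_tallies: dict[str, tuple[int, int]]  # gene_id -> (ns, syn)
    causal_group_ids: tuple[str, ...]
    artifact_sites: dict[str, list[tuple[str, int, str, str]]]

    def all_mutations(self) -> list[TrueMutation]:
        return [m for strain in self.strain_mutations for m in strain]


@dataclass
class SyntheticBundle:
    """Everything one synthetic experiment produced, in memory."""

    config: SyntheticConfig
    ref_seq: str
    genes: list[GeneModel]
    groups: list[GeneGroup]
    pool_calls: dict[str, list[VariantCall]]
    truth: TruthSet

    def all_calls(self) -> list[VariantCall]:
        return [c for calls in self.pool_calls.values() for c in calls]

    @property
    def pool_ids(self) -> list[str]:
        return list(self.pool_calls)


def generate(cfg: SyntheticConfig) -> SyntheticBundle:
    """Generate one experiment; bit-reproducible for a fixed seed."""
    rng = np.random.default_rng(cfg.seed)

    genome, genes, gene_of_pos = _make_genome(cfg, rng)
    groups, causal_members = _make_groups(cfg, genes, rng)
    causal_ids = tuple(gid for gid, _ in causal_members)

    used: set[int] = set()
    strain_muts: list[list[TrueMutation]] = [[] for _ in range(cfg.n_strains)]

    # causal hits first, so background sampling can avoid their sites
    for (group_id, member_idx), spec in zip(causal_members, cfg.causal_groups):
        if not member_idx:
            raise ValueError(f"causal group {group_id} has no genes")
        for strain in range(cfg.n_strains):
            if spec.per_strain_prob is not None:
                n_hits = int(rng.random() < spec.per_strain_prob)
            else:
                n_hits = spec.hits_per_strain
            for _ in range(n_hits):
                mut = _place_nonsynonymous(
                    genes, member_idx, genome, used, rng, strain, group_id
                )
                strain_muts[strain].append(mut)

    _place_background(cfg, genome, gene_of_pos, genes, used, strain_muts, rng)

    gene_tallies = _truth_tallies(strain_muts, genes)
    pool_calls, artifact_sites = _make_pool_calls(cfg, genome, used, strain_muts, rng)

    truth = TruthSet(
        strain_mutations=strain_muts,
        gene_tallies=gene_tallies,
        causal_group_ids=causal_ids,
        artifact_sites=artifact_sites,
    )
    return SyntheticBundle(
        config=cfg,
        ref_seq="".join(genome),
        genes=genes,
        groups=groups,
        pool_calls=pool_calls,
        truth=truth,
    )


# ---------------------------------------------------------------- internals


def _make_genome(cfg, rng):
    n_codons = rng.integers(
        cfg.gene_length_range[0] // 3, cfg.gene_length_range[1] // 3 + 1, cfg.n_genes
    )
    lengths = (n_codons * 3).astype(int)
    spacer = cfg.intergenic_length
    starts = np.empty(cfg.n_genes, dtype=int)
    pos = spacer
    for i, L in enumerate(lengths):
        starts[i] = pos
        pos += L + spacer
    genome_len = pos
    p_gc = cfg.gc_content / 2
    p_at = (1 - cfg.gc_content) / 2
    genome = rng.choice(_BASES, size=genome_len, p=[p_at, p_gc, p_gc, p_at])
    strands = rng.choice(np.array([1, -1]), size=cfg.n_genes)

    genes: list[GeneModel] = []
    gene_of_pos = np.full(genome_len, -1, dtype=np.int32)
    for i in range(cfg.n_genes):
        s, e = int(starts[i]), int(starts[i] + lengths[i])
        span = "".join(genome[s:e])
        coding = span if strands[i] > 0 else str(Seq(span).reverse_complement())
        gc = span.count("G") + span.count("C")
        genes.append(
            GeneModel(
                gene_id=f"g{i:04d}",
                strand=int(strands[i]),
                cds_intervals=((s, e),),
                coding_sequence=coding,
                gc_sites=gc,
                at_sites=len(span) - gc,
                locus_tag=f"SYN{i:04d}",
                gene_symbol=f"g{i:04d}",
            )
        )
        gene_of_pos[s:e] = i
    return genome, genes, gene_of_pos


def _make_groups(cfg, genes, rng):
    lo, hi = cfg.group_size_range
    groups: list[GeneGroup] = []
    for j in range(cfg.n_groups):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(len(genes), size=min(size, len(genes)), replace=False)
        groups.append(
            GeneGroup(
                group_id=f"GRP{j:04d}",
                members=frozenset(genes[int(m)].gene_id for m in members),
            )
        )
    # overwrite randomly chosen groups with the implanted causal gene sets
    causal_members: list[tuple[str, list[int]]] = []
    if cfg.causal_groups:
        idx = rng.choice(cfg.n_groups, size=len(cfg.causal_groups), replace=False)
        taken: set[int] = set()
        for j, spec in zip(idx, cfg.causal_groups):
            pool = [i for i in range(len(genes)) if i not in taken]
            chosen = [int(i) for i in rng.choice(pool, size=spec.n_genes, replace=False)]
            taken.update(chosen)
            gid = groups[int(j)].group_id
            groups[int(j)] = GeneGroup(
                group_id=gid,
                members=frozenset(genes[i].gene_id for i in chosen),
            )
            causal_members.append((gid, chosen))
    return groups, causal_members


def _classify_at(gene: GeneModel, pos0: int, ref: str, alt: str, table: int = 11) -> str:
    offset = gene.coding_offset(pos0)
    if gene.strand < 0:
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    ci, within = divmod(offset, 3)
    codon = gene.coding_sequence[3 * ci : 3 * ci + 3]
    mutated = codon[:within] + alt + codon[within + 1 :]
    return SYNONYMOUS if translate_codon(codon, table) == translate_codon(mutated, table) else NONSYNONYMOUS


def _place_nonsynonymous(genes, member_idx, genome, used, rng, strain, group_id):
    """Pick an unused CDS site in one of the member genes and an alt that
    changes the amino acid."""
    for _ in range(1000):
        gene = genes[int(rng.choice(member_idx))]
        s, e = gene.cds_intervals[0]
        pos0 = int(rng.integers(s, e))
        if pos0 in used:
            continue
        ref = genome[pos0]
        alts = [b for b in "ACGT" if b != ref]
        rng.shuffle(alts)
        for alt in alts:
            if _classify_at(gene, pos0, ref, alt) == NONSYNONYMOUS:
                used.add(pos0)
                return TrueMutation(
                    strain=strain,
                    pos=pos0 + 1,
                    ref=ref,
                    alt=alt,
                    gene_id=gene.gene_id,
                    effect=NONSYNONYMOUS,
                    causal_group=group_id,
                )
    raise RuntimeError(f"could not place a nonsynonymous mutation in {group_id}")


def _draw_sites(pool: np.ndarray, n: int, used: set[int], rng) -> list[int]:
    """n distinct positions from ``pool`` avoiding ``used``."""
    if n == 0:
        return []
    pad = max(64, len(used))
    take = min(len(pool), n + pad)
    cand = rng.choice(pool, size=take, replace=False)
    out = [int(p) for p in cand if int(p) not in used][:n]
    if len(out) < n:
        raise RuntimeError("not enough free sites for background mutations")
    used.update(out)
    return out


def _mutate_base(ref: str, transition_bias: float, rng) -> str:
    if rng.random() < transition_bias:
        return _TRANSITION[ref]
    return _TRANSVERSIONS[ref][int(rng.integers(2))]


def _place_background(cfg, genome, gene_of_pos, genes, used, strain_muts, rng):
    is_gc = (genome == "G") | (genome == "C")
    gc_pool = np.nonzero(is_gc)[0]
    at_pool = np.nonzero(~is_gc)[0]
    n_gc_per_strain: list[int] = []
    n_at_per_strain: list[int] = []
    for strain in range(cfg.n_strains):
        n_bg = max(0, cfg.mutations_per_strain - len(strain_muts[strain]))
        n_gc = int(rng.binomial(n_bg, cfg.gc_mutation_bias))
        n_gc_per_strain.append(n_gc)
        n_at_per_strain.append(n_bg - n_gc)
    gc_sites = _draw_sites(gc_pool, sum(n_gc_per_strain), used, rng)
    at_sites = _draw_sites(at_pool, sum(n_at_per_strain), used, rng)
    i_gc = i_at = 0
    for strain in range(cfg.n_strains):
        sites = (
            gc_sites[i_gc : i_gc + n_gc_per_strain[strain]]
            + at_sites[i_at : i_at + n_at_per_strain[strain]]
        )
        i_gc += n_gc_per_strain[strain]
        i_at += n_at_per_strain[strain]
        for pos0 in sites:
            ref = genome[pos0]
            alt = _mutate_base(ref, cfg.transition_bias, rng)
            gi = int(gene_of_pos[pos0])
            if gi < 0:
                gene_id = effect = None
            else:
                gene_id = genes[gi].gene_id
                effect = _classify_at(genes[gi], pos0, ref, alt)
            strain_muts[strain].append(
                TrueMutation(
                    strain=strain,
                    pos=pos0 + 1,
                    ref=ref,
                    alt=alt,
                    gene_id=gene_id,
                    effect=effect,
                    causal_group=None,
                )
            )


def _truth_tallies(strain_muts, genes) -> dict[str, tuple[int, int]]:
    ns = {g.gene_id: 0 for g in genes}
    syn = {g.gene_id: 0 for g in genes}
    for muts in strain_muts:
        for m in muts:
            if m.gene_id is None:
                continue
            if m.effect == NONSYNONYMOUS:
                ns[m.gene_id] += 1
            else:
                syn[m.gene_id] += 1
    return {g.gene_id: (ns[g.gene_id], syn[g.gene_id]) for g in genes}


def _make_pool_calls(cfg, genome, used, strain_muts, rng):
    pool_ids = [f"pool{i + 1}" for i in range(cfg.n_pools)]
    pool_calls: dict[str, list[VariantCall]] = {p: [] for p in pool_ids}
    af0 = 1.0 / cfg.pool_size

    def jittered_af():
        return float(np.clip(af0 + rng.normal(0.0, cfg.af_jitter_sd), 0.02, 1.0))

    def qual():
        return float(rng.uniform(*cfg.qual_range))

    def sb():
        return float(rng.uniform(0.01, 1.0))

    for strain, muts in enumerate(strain_muts):
        pid = pool_ids[strain // cfg.pool_size]
        for m in muts:
            pool_calls[pid].append(
                VariantCall(
                    chrom=CONTIG,
                    pos=m.pos,
                    ref=m.ref,
                    alt=m.alt,
                    qual=qual(),
                    pool_id=pid,
                    allele_freq=jittered_af(),
                    strand_bias_p=sb(),
                )
            )

    artifact_sites: dict[str, list[tuple[str, int, str, str]]] = {
        "low_qual": [], "strand_bias": [], "high_af": [], "parental": [],
    }
    genome_len = len(genome)

    def fresh_site() -> tuple[int, str, str]:
        while True:
            pos0 = int(rng.integers(genome_len))
            if pos0 not in used:
                used.add(pos0)
                ref = genome[pos0]
                return pos0, ref, _mutate_base(ref, cfg.transition_bias, rng)

    for _ in range(cfg.n_low_qual):
        pos0, ref, alt = fresh_site()
        pid = pool_ids[int(rng.integers(cfg.n_pools))]
        pool_calls[pid].append(
            VariantCall(CONTIG, pos0 + 1, ref, alt, float(rng.uniform(20, 80)),
                        pid, jittered_af(), sb())
        )
        artifact_sites["low_qual"].append((CONTIG, pos0 + 1, ref, alt))
    for _ in range(cfg.n_strand_bias):
        pos0, ref, alt = fresh_site()
        pid = pool_ids[int(rng.integers(cfg.n_pools))]
        pool_calls[pid].append(
            VariantCall(CONTIG, pos0 + 1, ref, alt, qual(), pid,
                        jittered_af(), float(10.0 ** rng.uniform(-8, -4.5)))
        )
        artifact_sites["strand_bias"].append((CONTIG, pos0 + 1, ref, alt))
    for _ in range(cfg.n_high_af):
        pos0, ref, alt = fresh_site()
        pid = pool_ids[int(rng.integers(cfg.n_pools))]
        pool_calls[pid].append(
            VariantCall(CONTIG, pos0 + 1, ref, alt, qual(), pid,
                        float(rng.uniform(0.6, 0.95)), sb())
        )
        artifact_sites["high_af"].append((CONTIG, pos0 + 1, ref, alt))
    for _ in range(cfg.n_parental):
        # injected with pool-typical AF so it reaches the multi-pool stage
        pos0, ref, alt = fresh_site()
        for pid in pool_ids:
            pool_calls[pid].append(
                VariantCall(CONTIG, pos0 + 1, ref, alt, qual(), pid,
                            jittered_af(), sb())
            )
        artifact_sites["parental"].append((CONTIG, pos0 + 1, ref, alt))

    return pool_calls, artifact_sites


# ------------------------------------------------------------------ writing


def to_seqrecord(bundle: SyntheticBundle) -> SeqRecord:
    """The synthetic genome as an annotated (circular) GenBank record."""
    rec = SeqRecord(
        Seq(bundle.ref_seq),
        id=CONTIG,
        name=CONTIG,
        description="synthetic mutagenesis reference",
    )
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["topology"] = "circular"
    for g in bundle.genes:
        (s, e), = g.cds_intervals
        rec.features.append(
            SeqFeature(
                SimpleLocation(s, e, strand=g.strand),
                type="CDS",
                qualifiers={"gene": [g.gene_symbol], "locus_tag": [g.locus_tag]},
            )
        )
    return rec


def write_bundle(bundle: SyntheticBundle, out_dir) -> dict[str, Path]:
    """Write genome.gb, groups.tsv, per-pool VCFs and truth.json.

    Returns a mapping of artifact names to paths (pool VCFs under their
    pool ids).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    genome_path = out / "genome.gb"
    SeqIO.write(to_seqrecord(bundle), str(genome_path), "genbank")
    paths["genome"] = genome_path

    groups_path = out / "groups.tsv"
    with open(groups_path, "w") as fh:
        for grp in bundle.groups:
            fh.write(f"{grp.group_id}\t{' '.join(sorted(grp.members))}\n")
    paths["groups"] = groups_path

    contigs = {CONTIG: len(bundle.ref_seq)}
    for pid, calls in bundle.pool_calls.items():
        vcf_path = out / f"{pid}.vcf"
        write_pool_vcf(calls, vcf_path, contigs)
        paths[pid] = vcf_path

    truth_path = out / "truth.json"
    with open(truth_path, "w") as fh:
        json.dump(
            {
                "causal_group_ids": list(bundle.truth.causal_group_ids),
                "gene_tallies": {k: list(v) for k, v in bundle.truth.gene_tallies.items()},
                "artifact_sites": bundle.truth.artifact_sites,
                "strain_mutations": [
                    [asdict(m) for m in muts] for muts in bundle.truth.strain_mutations
                ],
            },
            fh,
            indent=1,
        )
    paths["truth"] = truth_path
    log.info("wrote synthetic bundle to %s", out)
    return paths
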