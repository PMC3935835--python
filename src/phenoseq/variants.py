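"""Reading and filtering pooled-sequencing variant calls.

A phenotype-sequencing experiment pools a few independently mutagenized
strains per tagged library, calls variants per pool (samtools mpileup /
bcftools dialect), and needs a clean SNP set before any scoring: calls with
adequate quality, no strand-bias artifacts, per-pool allele frequency
consistent with a single carrier strain, and no variants shared across
pools (those are parental differences from the reference, not induced
mutations).

This module reads per-pool VCFs into :class:`VariantCall` records and
applies that four-stage filter cascade in order: quality, strand bias,
allele frequency, multi-pool.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pysam

log = logging.getLogger(__name__)

_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class VariantCall:
    """One called single-nucleotide substitution in one pool.

    ``pos`` is the 1-based genomic coordinate as printed in the VCF; all
    internal interval arithmetic converts to 0-based half-open at module
    boundaries. ``allele_freq`` is the estimated alternate-allele fraction
    in the pool; ``strand_bias_p`` is a p-value where smaller means more
    biased. Either may be absent (``None``) when the caller did not emit
    the field.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    qual: float
    pool_id: str
    allele_freq: float | None = None
    strand_bias_p: float | None = None

    def __post_init__(self) -> None:
        if self.ref not in _BASES or self.alt not in _BASES:
            raise ValueError(
                f"ref/alt must be single bases in ACGT, got {self.ref!r}>{self.alt!r}"
            )
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.allele_freq is not None and not 0.0 <= self.allele_freq <= 1.0:
            raise ValueError(f"allele_freq out of [0,1]: {self.allele_freq}")

    @property
    def site(self) -> tuple[str, int, str, str]:
        """Identity of the substitution irrespective of pool."""
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class FilterConfig:
    """Thresholds for the four-stage filter cascade.

    qual_min
        Phred-scaled call quality; calls must be *strictly greater* to pass
        (default 90).
    af_max
        Per-pool allele-frequency ceiling; calls strictly above are removed
        (default 0.5, i.e. more than half the pool carries the allele).
    strand_bias_p_min
        Minimum acceptable strand-bias p-value (default 1e-4). Calls
        lacking the field pass this stage.
    max_pools
        Maximum number of distinct pools a substitution may appear in
        before it is called parental (default 1: every induced mutation
        belongs to exactly one strain, hence one pool).
    """

    qual_min: float = 90.0
    af_max: float = 0.5
    strand_bias_p_min: float = 1e-4
    max_pools: int = 1

    def __post_init__(self) -> None:
        if self.qual_min < 0:
            raise ValueError("qual_min must be >= 0")
        if not 0.0 < self.af_max <= 1.0:
            raise ValueError("af_max must be in (0, 1]")
        if self.max_pools < 1:
            raise ValueError("max_pools must be >= 1")


#: Stage names, in the order the cascade applies them.
FILTER_STAGES = ("qual", "strand_bias", "allele_freq", "multi_pool")


@dataclass
class FilterReport:
    """Per-stage exclusion bookkeeping.

    ``calls`` counts removed VariantCall records and sums, together with
    the kept set, to the input size. ``sites`` counts distinct
    (chrom, pos, ref, alt) substitutions removed per stage — for the
    multi-pool stage one parental variant present in all pools counts once
    here but once per pool in ``calls``.
    """

    calls: dict[str, int] = field(
        default_factory=lambda: {s: 0 for s in FILTER_STAGES}
    )
    sites: dict[str, int] = field(
        default_factory=lambda: {s: 0 for s in FILTER_STAGES}
    )

    @property
    def total_removed(self) -> int:
        return sum(self.calls.values())


def read_pool_vcf(
    path,
    pool_id: str,
    *,
    af_key: str = "AF1",
    sb_key: str = "PV4",
) -> list[VariantCall]:
    """Read one pool's VCF into a list of :class:`VariantCall`.

    Only single-nucleotide substitutions are retained; indels and MNPs are
    skipped (counted and logged). Multi-allelic SNP records are split into
    one call per alternate allele. The allele-frequency estimate is read
    from INFO key ``af_key`` and the strand-bias p-value from the first
    component of INFO key ``sb_key`` (the samtools PV4 convention); missing
    fields yield ``None`` with a single warning per file.
    """
    try:
        vcf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read VCF {path}: {exc}") from exc

    calls: list[VariantCall] = []
    n_skipped = 0
    warned: set[str] = set()
    with vcf:
        for rec in vcf:
            ref = (rec.ref or "").upper()
            for i, alt in enumerate(rec.alts or ()):
                alt = alt.upper()
                if len(ref) != 1 or len(alt) != 1 or ref not in _BASES or alt not in _BASES:
                    n_skipped += 1
                    continue
                af = _info_scalar(rec, af_key, i)
                if af is None and af_key not in warned:
                    warned.add(af_key)
                    log.warning("%s: INFO/%s absent; allele-frequency filter will pass", path, af_key)
                sb = _info_first(rec, sb_key)
                if sb is None and sb_key not in warned:
                    warned.add(sb_key)
                    log.warning("%s: INFO/%s absent; strand-bias filter will pass", path, sb_key)
                calls.append(
                    VariantCall(
                        chrom=rec.chrom,
                        pos=rec.pos,  # pysam reports the 1-based VCF POS
                        ref=ref,
                        alt=alt,
                        qual=float(rec.qual) if rec.qual is not None else 0.0,
                        pool_id=pool_id,
                        allele_freq=af,
                        strand_bias_p=sb,
                    )
                )
    if n_skipped:
        log.info("%s: skipped %d non-SNP allele(s)", path, n_skipped)
    return calls


def _info_scalar(rec, key: str, alt_index: int) -> float | None:
    """INFO value as a float; per-alt tuples indexed by alternate allele."""
    if key not in rec.info:
        return None
    val = rec.info[key]
    if isinstance(val, (tuple, list)):
        if not val:
            return None
        val = val[alt_index] if alt_index < len(val) else val[0]
    return float(val) if val is not None else None


def _info_first(rec, key: str) -> float | None:
    """First component of a (possibly vector) INFO value, as a float."""
    if key not in rec.info:
        return None
    val = rec.info[key]
    if isinstance(val, (tuple, list)):
        val = val[0] if val else None
    return float(val) if val is not None else None


def filter_variants(
    calls: Iterable[VariantCall],
    cfg: FilterConfig | None = None,
) -> tuple[list[VariantCall], FilterReport]:
    """Apply the four-stage cascade; return (kept calls, exclusion report).

    Stages apply in order — quality, strand bias, allele frequency,
    multi-pool — and each removed call is attributed to the first stage
    that rejects it. The multi-pool stage operates on the survivors of the
    first three: a substitution seen in more than ``cfg.max_pools``
    distinct pools is removed from all of them (parental variant).

    The result set is insensitive to input ordering, and the cascade is
    idempotent: filtering the kept set again removes nothing.
    """
    cfg = cfg if cfg is not None else FilterConfig()
    report = FilterReport()
    survivors: list[VariantCall] = []
    removed_sites: dict[str, set] = {s: set() for s in FILTER_STAGES}

    for c in calls:
        if not c.qual > cfg.qual_min:
            report.calls["qual"] += 1
            removed_sites["qual"].add(c.site)
        elif c.strand_bias_p is not None and c.strand_bias_p < cfg.strand_bias_p_min:
            report.calls["strand_bias"] += 1
            removed_sites["strand_bias"].add(c.site)
        elif c.allele_freq is not None and c.allele_freq > cfg.af_max:
            report.calls["allele_freq"] += 1
            removed_sites["allele_freq"].add(c.site)
        else:
            survivors.append(c)

    pools_per_site: dict[tuple, set[str]] = defaultdict(set)
    for c in survivors:
        pools_per_site[c.site].add(c.pool_id)

    kept: list[VariantCall] = []
    for c in survivors:
        if len(pools_per_site[c.site]) > cfg.max_pools:
            report.calls["multi_pool"] += 1
            removed_sites["multi_pool"].add(c.site)
        else:
            kept.append(c)

    for stage in FILTER_STAGES:
        report.sites[stage] = len(removed_sites[stage])
    log.info(
        "filter cascade (qual>%g, sb_p>=%g, af<=%g, pools<=%d): kept %d, removed %s",
        cfg.qual_min, cfg.strand_bias_p_min, cfg.af_max, cfg.max_pools,
        len(kept), report.calls,
    )
    return kept, report
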