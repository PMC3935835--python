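"""End-to-end orchestration: VCFs + genome + groups in, report bundle out.

Runs the published analysis order — filter, annotate, tally, score genes
and pathways, cumulative positive-selection tests, top-gene enrichment,
causal-mutation estimates — writing every table as TSV plus a JSON
manifest of versions, thresholds and input paths. Output is a pure
function of (inputs, config); any stage failure aborts with the stage
name and cause.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .annotation import annotate_all, load_genome
from .causal import estimate_causal
from .enrichment import enrich
from .io import annotated_to_tsv, records_to_tsv, variants_to_tsv
from .pathways import load_groups, resolve_groups, tally_genes, tally_groups
from .scoring import estimate_densities, score_units
from .selection import cumulative_selection, selection_excluding
from .variants import FilterConfig, filter_variants, read_pool_vcf

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    genome: Path
    groups: Path
    vcfs: Sequence[tuple[str, Path]]  # (pool_id, path)
    out_dir: Path
    filter_cfg: FilterConfig = field(default_factory=FilterConfig)
    af_key: str = "AF1"
    sb_key: str = "PV4"
    density_mode: str = "nonsynonymous"
    n_tests: int | None = None  # default: total number of groups loaded
    top_k: int = 50
    n_selection_groups: int = 10
    exclude_genes: tuple[str, ...] = ()
    translation_table: int = 11


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc
        return wrapper
    return deco


def run_pipeline(cfg: RunConfig) -> dict[str, Path]:
    """Run every stage; return a mapping of output names to paths."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    ref_seq, genes = _stage("load_genome")(load_genome)(cfg.genome)
    raw_groups = _stage("load_groups")(load_groups)(cfg.groups)
    groups = _stage("resolve_groups")(resolve_groups)(raw_groups, genes)

    @_stage("read_vcfs")
    def _read():
        calls = []
        for pool_id, path in cfg.vcfs:
            calls.extend(
                read_pool_vcf(path, pool_id, af_key=cfg.af_key, sb_key=cfg.sb_key)
            )
        return calls

    calls = _read()
    kept, report = _stage("filter")(filter_variants)(calls, cfg.filter_cfg)
    paths["filtered"] = out / "filtered_variants.tsv"
    variants_to_tsv(kept, paths["filtered"])
    paths["filter_report"] = out / "filter_report.tsv"
    pd.DataFrame(
        {
            "stage": list(report.calls),
            "calls_removed": list(report.calls.values()),
            "sites_removed": list(report.sites.values()),
        }
    ).to_csv(paths["filter_report"], sep="\t", index=False)

    annotated = _stage("annotate")(annotate_all)(
        kept, genes, ref_seq, table=cfg.translation_table
    )
    paths["annotated"] = out / "annotated_mutations.tsv"
    annotated_to_tsv(annotated, paths["annotated"])

    gene_tallies = tally_genes(annotated, genes)
    group_tallies = tally_groups(gene_tallies, groups)
    dens = _stage("densities")(estimate_densities)(annotated, ref_seq, cfg.density_mode)

    score_cols = ("rank", "unit_id", "n_obs", "lam", "p_raw", "p_corr")
    gene_scores = _stage("score_genes")(score_units)(
        list(gene_tallies.values()), dens, len(genes)
    )
    paths["gene_scores"] = out / "gene_scores.tsv"
    records_to_tsv(gene_scores, paths["gene_scores"], score_cols)

    n_tests = cfg.n_tests if cfg.n_tests is not None else len(groups)
    group_scores = _stage("score_pathways")(score_units)(group_tallies, dens, n_tests)
    paths["pathway_scores"] = out / "pathway_scores.tsv"
    records_to_tsv(group_scores, paths["pathway_scores"], score_cols)

    # genome-wide totals over CDS-mapped mutations
    ns_tot = sum(t.ns for t in gene_tallies.values())
    syn_tot = sum(t.syn for t in gene_tallies.values())

    group_by_id = {g.group_id: g for g in groups}
    ranked = [
        group_by_id[r.unit_id]
        for r in group_scores[: cfg.n_selection_groups]
        if r.unit_id in group_by_id
    ]

    @_stage("selection")
    def _selection():
        rows = cumulative_selection(ranked, gene_tallies, ns_tot, syn_tot)
        if cfg.exclude_genes:
            rows.append(
                selection_excluding(ranked, cfg.exclude_genes, gene_tallies, ns_tot, syn_tot)
            )
        return rows

    paths["selection"] = out / "selection.tsv"
    records_to_tsv(
        _selection(), paths["selection"],
        ("label", "ns_in", "syn_in", "ns_tot", "syn_tot", "p", "ka_ks_like"),
    )

    @_stage("enrichment")
    def _enrich():
        universe = [t.unit_id for t in gene_tallies.values() if t.ns > 0]
        ranked_genes = [r.unit_id for r in gene_scores if r.unit_id in set(universe)]
        top = ranked_genes[: cfg.top_k]
        return enrich(top, groups, universe) if top else []

    paths["enrichment"] = out / "enrichment.tsv"
    records_to_tsv(
        _enrich(), paths["enrichment"],
        ("rank", "group_id", "k_in_top", "group_size", "K_top", "n_candidates", "p_raw", "p_corr"),
    )

    @_stage("causal")
    def _causal():
        if ns_tot + syn_tot == 0:
            return []
        f0 = ns_tot / (ns_tot + syn_tot)
        tally_by_id = {t.unit_id: t for t in group_tallies}
        ests = []
        for rec in group_scores[: cfg.n_selection_groups]:
            t = tally_by_id[rec.unit_id]
            if t.n_total >= 1 and 0.0 < f0 < 1.0:
                ests.append(estimate_causal(t.ns, t.syn, f0, unit_id=t.unit_id))
        return ests

    paths["causal"] = out / "causal_estimates.tsv"
    records_to_tsv(
        _causal(), paths["causal"],
        ("unit_id", "n_total", "x", "f0", "c_raw", "c", "n_causal", "n_causal_frac"),
    )

    manifest = {
        "phenoseq_version": __version__,
        "genome": str(cfg.genome),
        "groups": str(cfg.groups),
        "vcfs": {pid: str(p) for pid, p in cfg.vcfs},
        "filter": {
            "qual_min": cfg.filter_cfg.qual_min,
            "af_max": cfg.filter_cfg.af_max,
            "strand_bias_p_min": cfg.filter_cfg.strand_bias_p_min,
            "max_pools": cfg.filter_cfg.max_pools,
            "af_key": cfg.af_key,
            "sb_key": cfg.sb_key,
        },
        "density_mode": cfg.density_mode,
        "n_tests": n_tests,
        "top_k": cfg.top_k,
        "exclude_genes": list(cfg.exclude_genes),
        "translation_table": cfg.translation_table,
        "totals": {"ns": ns_tot, "syn": syn_tot},
        "n_calls_in": len(calls),
        "n_kept": len(kept),
    }
    paths["manifest"] = out / "manifest.json"
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    log.info("pipeline complete: %d outputs in %s", len(paths), out)
    return paths
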