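"""Poisson mutational-target scoring: densities, cross-sections, p-values."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from phenoseq.annotation import NONSYNONYMOUS, SYNONYMOUS, AnnotatedMutation
from phenoseq.pathways import MutationTally
from phenoseq.scoring import (
    SiteDensities,
    cross_section,
    estimate_densities,
    genome_site_counts,
    poisson_pvalue,
    score_units,
)

from conftest import make_call


def _ann(ref, effect=NONSYNONYMOUS, pos=1):
    hits = ((("gX", 0, effect),) if effect is not None else ())
    return AnnotatedMutation(make_call(pos, ref=ref, alt="T" if ref != "T" else "A"), hits)


class TestDensities:
    def test_all_gc_mutations(self):
        genome = "G" * 100 + "A" * 100
        anns = [_ann("G", pos=i + 1) for i in range(10)]
        d = estimate_densities(anns, genome, mode="all")
        assert d.rho_gc == pytest.approx(0.1)
        assert d.rho_at == 0.0
        assert d.n_mutations_used == 10

    def test_ntg_like_ratio(self):
        """90 GC-site + 10 AT-site mutations on a 300 GC / 100 AT genome:
        direct counting gives rho_gc/rho_at = (90/300)/(10/100) = 3."""
        genome = "C" * 300 + "T" * 100
        anns = [_ann("C") for _ in range(90)] + [_ann("T") for _ in range(10)]
        d = estimate_densities(anns, genome, mode="all")
        assert d.rho_gc / d.rho_at == pytest.approx(3.0)

    def test_mode_nonsynonymous_excludes_other_classes(self):
        genome = "G" * 50 + "A" * 50
        anns = [_ann("G", NONSYNONYMOUS), _ann("G", SYNONYMOUS), _ann("G", None)]
        d = estimate_densities(anns, genome, mode="nonsynonymous")
        assert d.n_mutations_used == 1
        d_all = estimate_densities(anns, genome, mode="all")
        assert d_all.n_mutations_used == 3

    def test_empty_mutations_warns_and_zero(self, caplog):
        d = estimate_densities([], "GATC" * 10, mode="all")
        assert d.rho_gc == 0.0 and d.rho_at == 0.0

    def test_single_base_genome_is_error(self):
        with pytest.raises(ValueError):
            estimate_densities([], "GGGG", mode="all")

    def test_bad_mode(self):
        with pytest.raises(ValueError):
            estimate_densities([], "GATC", mode="nonsense")

    def test_genome_site_counts(self):
        assert genome_site_counts("GGCCAATT") == (4, 4)


class TestCrossSection:
    def test_single_term(self):
        d = SiteDensities(0.01, 0.0, 1, "all")
        assert cross_section(MutationTally("u", 0, 0, 300, 0), d) == pytest.approx(3.0)

    def test_two_terms(self):
        d = SiteDensities(0.02, 0.005, 1, "all")
        assert cross_section(MutationTally("u", 0, 0, 200, 100), d) == pytest.approx(4.5)

    def test_group_lambda_additive_over_members(self):
        d = SiteDensities(0.013, 0.007, 1, "all")
        a = MutationTally("a", 0, 0, 120, 80)
        b = MutationTally("b", 0, 0, 30, 270)
        merged = MutationTally("ab", 0, 0, 150, 350)
        assert cross_section(merged, d) == pytest.approx(
            cross_section(a, d) + cross_section(b, d))


def _tail_oracle(n: int, lam: float) -> float:
    """Independent upper-tail sum of the Poisson pmf via log terms + fsum."""
    if n == 0:
        return 1.0
    kmax = int(max(n, lam) + 60 * math.sqrt(lam) + 60)
    terms = [math.exp(k * math.log(lam) - lam - math.lgamma(k + 1))
             for k in range(n, kmax + 1)]
    return math.fsum(reversed(terms))


class TestPoissonPvalue:
    def test_zero_observed_is_one(self):
        for lam in (0.01, 1.0, 40.0):
            assert poisson_pvalue(0, lam) == 1.0

    def test_closed_forms(self):
        # P(X>=3 | 0.5) = 1 - e^-0.5 (1 + 0.5 + 0.125)
        assert poisson_pvalue(3, 0.5) == pytest.approx(0.014387677966970684, rel=1e-12)
        # P(X>=2 | 1) = 1 - 2/e
        assert poisson_pvalue(2, 1.0) == pytest.approx(1 - 2 / math.e, rel=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            poisson_pvalue(1, 0.0)
        with pytest.raises(ValueError):
            poisson_pvalue(-1, 1.0)

    @pytest.mark.parametrize("lam", [0.1, 0.5, 1.0, 2.0, 5.0, 10.0, 20.0, 50.0])
    def test_matches_pmf_summation_oracle(self, lam):
        for n in range(0, 201, 7):
            expected = _tail_oracle(n, lam)
            got = poisson_pvalue(n, lam)
            if expected > 1e-300:
                assert got == pytest.approx(expected, rel=1e-12), (n, lam)

    @given(st.integers(1, 60), st.floats(0.1, 30.0))
    def test_decreasing_in_n_increasing_in_lam(self, n, lam):
        assert poisson_pvalue(n + 1, lam) < poisson_pvalue(n, lam)
        assert poisson_pvalue(n, lam * 1.5) > poisson_pvalue(n, lam)


class TestScoreUnits:
    DENS = SiteDensities(0.01, 0.01, 100, "all")

    def test_more_observed_ranks_first_at_equal_lambda(self):
        tallies = [MutationTally("low", 1, 0, 100, 100),
                   MutationTally("high", 5, 0, 100, 100)]
        recs = score_units(tallies, self.DENS, 10)
        assert [r.unit_id for r in recs] == ["high", "low"]
        assert recs[0].rank == 1

    def test_bonferroni_multiplication_and_cap(self):
        tallies = [MutationTally("u", 8, 0, 100, 100)]
        (rec,) = score_units(tallies, self.DENS, 536)
        assert rec.p_corr == pytest.approx(min(1.0, rec.p_raw * 536))
        p = 0.001
        assert min(1.0, p * 536) == pytest.approx(0.536)

    def test_deterministic_tie_break_by_id(self):
        tallies = [MutationTally(uid, 2, 0, 100, 100) for uid in ("b", "a", "c")]
        recs = score_units(tallies, self.DENS, 3)
        assert [r.unit_id for r in recs] == ["a", "b", "c"]

    def test_gene_order_invariance(self):
        tallies = [MutationTally(f"u{i}", i % 4, 0, 50 + i, 50) for i in range(12)]
        fwd = score_units(tallies, self.DENS, 12)
        rev = score_units(list(reversed(tallies)), self.DENS, 12)
        assert [r.unit_id for r in fwd] == [r.unit_id for r in rev]


def test_null_pvalues_super_uniform_over_simulated_genomes():
    """With no implanted causal group, the fraction of group scores below
    0.05 stays within binomial noise of 0.05 across many small simulated
    mutagenesis experiments (the Poisson null is honest or conservative)."""
    from phenoseq.annotation import annotate_all
    from phenoseq.pathways import tally_genes, tally_groups
    from phenoseq.synth import SyntheticConfig, generate

    n_below = n_total = 0
    for rep in range(200):
        cfg = SyntheticConfig(
            n_genes=40, n_groups=60, group_size_range=(2, 8),
            n_strains=4, pool_size=2, n_pools=2, mutations_per_strain=60,
            gene_length_range=(300, 900), seed=10_000 + rep,
        )
        b = generate(cfg)
        anns = annotate_all(b.all_calls(), b.genes, b.ref_seq)
        dens = estimate_densities(anns, b.ref_seq, mode="nonsynonymous")
        tallies = tally_groups(tally_genes(anns, b.genes), b.groups)
        recs = score_units(tallies, dens, cfg.n_groups)
        n_below += sum(1 for r in recs if r.p_raw < 0.05)
        n_total += len(recs)
    frac = n_below / n_total
    sigma = math.sqrt(0.05 * 0.95 / n_total)
    assert frac <= 0.05 + 3 * sigma, (frac, n_total)
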