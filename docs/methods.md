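# Methods

## Setting

A phenotype-sequencing experiment produces K independently mutagenized,
phenotype-screened strains (here K = 24, NTG mutagenesis, ~100 point
mutations per strain), pooled m per tagged library (m = 3, 8 pools) and
sequenced. Variants are called per pool; a variant cannot be assigned to a
strain within its pool. The analysis asks which genes — and, pooling
signal across functionally associated genes, which gene groups — carry
more nonsynonymous mutations than neutral mutagenesis explains.

## Variant filtering

Four stages, in order, each call attributed to the first stage that
removes it:

1. **Quality** — QUAL strictly greater than `qual_min` (default 90).
2. **Strand bias** — strand-bias p-value at least `strand_bias_p_min`
   (default 10⁻⁴, configurable; calls lacking the field pass). The exact
   cutoff used in the reference screen is not recoverable from its
   description, so the threshold is an explicit, logged parameter rather
   than a claimed constant.
3. **Allele frequency** — per-pool AF at most `af_max` (default 0.5):
   with three distinct strains per pool, a real induced mutation is
   carried by one strain (AF ≈ 1/3).
4. **Multi-pool** — a substitution in more than `max_pools` (default 1)
   distinct pools is parental. The general "> max_pools" rule is
   implemented although in practice parental variants appear in *all*
   pools. The report counts removals both per call and per distinct
   variant, since one parental variant is many calls.

AF is read from INFO key `AF1` and strand bias from the first component
of `PV4` (samtools/bcftools convention); both keys are configurable. The
cascade is idempotent and order-insensitive, and only single-nucleotide
substitutions are considered (indels are counted and skipped).

## Effect annotation

CDS features come from a GenBank reference; each SNP is located by an
interval tree and classified per overlapping CDS by substituting the
(strand-complemented) allele into its codon and comparing translations
under NCBI table 11. Choices where the convention was open:

- stop-gain/stop-loss changes are nonsynonymous;
- start codons get no special handling (ordinary codon translation);
- a SNP in several overlapping CDSs contributes one hit per CDS;
- CDSs whose length is not a codon multiple are logged and excluded.

## Poisson mutational-target scoring

Genome-wide per-site densities ρ_GC, ρ_AT are the observed mutation counts
on G/C (resp. A/T) reference sites divided by the genome's G/C (A/T) site
counts. The default density mode is `nonsynonymous`: the density estimate
uses the same mutation class that is scored, making the null
self-consistent. Mode `all` (densities from every filtered mutation,
matching a looser reading of the published recipe) is available and
recorded in output headers; with ~2/3 of mutations nonsynonymous the two
modes scale all λ by a near-constant factor and the resulting rankings
are nearly identical.

A unit's cross-section is λ = n_GC·ρ_GC + n_AT·ρ_AT over its *genomic
span* composition — deliberately not a codon-position-aware
nonsynonymous-opportunity model, keeping the statistic as published. λ is
additive over group members. The score is the inclusive Poisson upper
tail P(X ≥ n_obs), computed via the survival function; Bonferroni
correction multiplies by the total size of the group database (536-style),
not the number of groups actually hit. Ranking ties break by descending
observed count, then unit id, so output is deterministic.

## Positive-selection and enrichment tests

The selection test is the one-tailed ("greater") Fisher exact test on
[[ns_in, syn_in], [ns_tot−ns_in, syn_tot−syn_in]]. Cumulative tests down
the ranked group list pool either the union of member genes (default —
a gene shared by nested groups counts once) or per-group sums (retained
because the reference table's bookkeeping for nested groups cannot be
uniquely inferred). No multiple-testing correction is applied to the
cumulative test: it is one test on one nested family. The reported
`ka_ks_like` value is the in-set ns/syn count ratio over the genome-wide
ratio, with no site-opportunity normalization (an ∞ flag when syn_in = 0).

Enrichment of the top-K gene-ranking inside groups uses the
hypergeometric tail with the candidate universe defaulting to genes
carrying at least one nonsynonymous mutation; group size is measured
inside that universe. K defaults to 50. Only groups intersecting the top
list are tested and the Bonferroni factor is their count.

### Discrepancy in the reference selection p-values

The reference screen reports cumulative selection p-values of 0.0037,
0.0044 and 0.000034 for in-set counts (34, 5), (52, 11) and (103, 21)
against totals (1450, 707). The exact one-tailed Fisher test — verified
identical in scipy and R to machine precision — gives 0.003828, 0.004651
and 3.697·10⁻⁵ for those counts, uniformly a few percent above the
reported values; no standard variant (tail excluding the observed table,
unsubtracted margins, background excluding the tested set, binomial or
Poisson approximations, mid-p) reproduces them. Notably the exact test on
(19, 1) — the counts of the single most-mutated gene in the top group —
gives 0.0037003, matching the first reported value to four decimals, so
the reported column was most likely computed from slightly different
counts than the published table prints. The acceptance test for these
values asserts the reported numbers at their printed precision and is
expected to fail; the same implementation reproduces the causal-count
column and the 103/21 column sums exactly.

## Causal-mutation estimator

With all causal mutations assumed nonsynonymous and non-causal mutations
neutral with background nonsynonymous fraction f₀, the observed fraction
x = ns/N satisfies x = c + (1−c)f₀, inverted to ĉ = (x−f₀)/(1−f₀). ĉ is
clamped to [0, 1] (the raw value is kept as a diagnostic; negative values
mean the unit is *less* nonsynonymous than background) and
n_causal = round(ĉ·N), half away from zero, with the fractional value also
emitted. f₀ defaults to the filtered dataset's own nonsynonymous fraction
(1450/2157 ≈ 0.672 in the reference screen) and can be overridden. The
estimator is deliberately simplistic — a point estimate without credible
intervals.

## Wright–Fisher simulator

Founders (one cell per strain, default 26) double deterministically each
generation; the generation doubling reaches the carrying capacity, the
population is multinomially down-sampled to exactly the capacity, and
every later generation resamples multinomially with probabilities
proportional to count × fitness. Selection therefore acts only from
capacity onward, the simplest reading of "grow exponentially to carrying
capacity". Diversity is tracked as distinct surviving strains and Shannon
entropy (base 2, bits). Per-strain fitnesses default to fresh
lognormal(0, σ) draws per replicate with σ = 0.3 — an explicit stand-in,
since the real fitness distribution of mutagenized strains is unknown;
the reported "half the strains lost within ~6–7 generations" behaviour is
therefore treated as qualitative (selective configurations must lose
diversity at least as fast as neutral ones), not as a numeric target.

## Synthetic data generator

The generator emulates the study conditions: a single circular contig
with `n_genes` = 500 non-overlapping CDSs (lengths uniform over 300–1500
bp rounded to codons, 20 bp spacers, 50% GC), a 536-group database with
group sizes uniform on 2–12, 24 strains × 100 mutations with 95% of
mutations on G/C sites and a 0.9 transition bias (NTG-like), pooled 3 per
library into 8 pools. Causal groups are implanted by forcing, per strain,
the configured number of nonsynonymous hits into randomly chosen member
genes. Background sites are drawn without replacement *across* strains:
independent mutants essentially never hit the same base, and this keeps
pool allele fractions exactly single-carrier. Pool AF is 1/pool_size plus
Gaussian jitter (σ = 0.03, clipped), QUAL uniform on 120–220, strand-bias
p uniform on 0.01–1.

Artifact injection adds calls violating exactly one filter each. Parental
artifacts are injected at pool-typical AF (not the realistic AF ≈ 1, which
the upstream AF filter would absorb) so the multi-pool rule is exercised
in isolation and per-filter bookkeeping stays exact.

What the generator does *not* emulate: read-level errors and coverage
fluctuations (AF jitter is the only noise), within-pool site collisions,
non-uniform gene spacing, operon structure, codon usage bias, and any
non-coding mutation process. Passing recovery tests therefore demonstrate
the statistics and plumbing under the stated design, not robustness to
alignment or calling artifacts upstream of the VCF.

## Problem sizes and numerical choices

- Recovery acceptance: 100 replicates at full study scale (500 genes,
  536 groups, 24×100 mutations); the implanted 2-gene group must rank
  first with corrected p < 0.05 in ≥ 95 of them. Null calibration pools
  ~6 700 group scores from 20 replicates without an implanted group and
  requires the p < 0.05 fraction within 3σ of 0.05.
- Wright–Fisher acceptance: capacity 2 000, 25 generations, 1 000
  replicates per configuration — small enough to run in seconds, large
  enough that mean-trajectory noise (≈0.001 bits) is well below the
  per-generation entropy decay.
- Poisson tails come from the scipy survival function and agree with
  direct pmf summation to 10⁻¹² relative error (λ ≤ 50, n ≤ 200); Fisher
  and hypergeometric tails agree with exact rational enumeration for
  small tables.
- All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; generation and simulation are
  bit-reproducible for a fixed seed.

## Known limitations

- The strand-bias cutoff and the reference selection p-values are not
  exactly recoverable (see above); gene-level p-values of the reference
  screen are not reproduction targets at all, as they derive from the raw
  sequencing data.
- The cross-section ignores codon-position-specific nonsynonymous
  opportunity; for strongly atypical codon compositions the Poisson null
  is only approximate.
- The causal estimator gives point estimates only, and the top-20 vs
  top-50 ambiguity in the reference enrichment table is resolved in favor
  of K = 50 (the value its text states).
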