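# Methods

This note documents the models and procedural choices behind `methyldmr`:
what each stage computes, the parameters that matter, what the synthetic
generator does and does not emulate, and the numerical conventions.

## Coordinates and data model

Internally every interval is 0-based half-open. The on-disk dialects keep
their native conventions: Bismark cytosine/CX reports and TAIR10-style TE
tables are 1-based inclusive; BED output is 0-based half-open. Strands are
never symmetrized: a CG dinucleotide contributes two independent cytosine
sites, one per strand, exactly as the extractor reports them.
Zero-coverage cytosines are kept in memory — they mark that a cytosine
*position* exists — but never count as covered sites and contribute no
counts to any level.

## Methylation levels

The per-site frequency is `count_meth / (count_meth + count_unmeth)` —
methylated over total reads, i.e. C over C+T in bisulfite space — and is
*missing* (NaN), never 0, at zero coverage. Every aggregate (50-nt bin,
100-bp metaprofile interval, region, genome × context) is the weighted
level: pooled methylated counts over pooled coverage. This makes
aggregation associative (binning then pooling equals direct pooling, a
tested invariant) and weights deeply covered sites accordingly. No
minimum-coverage filter is applied for level computation: any covered site
counts. Genome-wide levels are printed as percentages with 2 decimals;
summary-table percentages with 1 decimal.

## Metaprofiles

Features are aligned at the biological 5′ or 3′ end; minus-strand features
are flipped so "5′" is always biological. Counts are pooled per 100-bp
interval across all features over ±5 kb around the anchor, then divided
once per interval. In-body positions within a *discard* distance of the
end opposite the anchor (default 1500 nt for genes, 250 nt for TEs) are
masked: positions are discarded, not features, so a feature shorter than
the discard distance keeps its flanks while its whole body is masked.
Flank positions are never masked, even where they overlap a neighbouring
feature — no exclusion rule is imposed there. Averaging per-feature
interval levels instead of pooling counts is available via
`per_feature_mean=True` but is not the default, keeping a single weighted
convention throughout.

## DMR calling

Replicates of one genotype are pooled by summing counts per
(chromosome, position, strand) before calling; no replicate-dispersion
model is fitted (beta-binomial testing across replicates is out of scope).
Calling then proceeds per context:

1. **Scan.** Non-overlapping 50-nt tiling windows. A window is a candidate
   when both genotypes have ≥ 1 covered cytosine of the context in it and
   the absolute pooled level difference reaches the context threshold
   (CHH 0.10, CHG 0.20, CG 0.40). Tiling rather than sliding windows keeps
   the "separated by more than 100 nt" independence rule well defined.
2. **Merge.** Candidate windows whose gap (end-exclusive to next start,
   strand-agnostic) is ≤ 100 nt join one region; larger gaps split
   independent regions.
3. **Filter and test.** Each merged region is recomputed over *all*
   covered context sites it spans and kept when: length ≥ 100 nt; ≥ 20
   cytosine sites (by default positions covered by ≥ 1 read in *both*
   genotypes — uncovered positions carry no evidence; counting every
   annotated position instead is available via `site_count_mode`); the
   region-level difference itself re-passes the threshold (a merged region
   is a DMR by virtue of its own difference, not only its windows'); and a
   two-sided Fisher's exact test on the pooled table
   (wt_meth, wt_unmeth) vs (mut_meth, mut_unmeth) gives p < 0.001. No
   multiple-testing correction is applied: the raw p-value bound is the
   stated rule.

Direction is the mutant relative to wild-type (hypo when lower). Every
emitted DMR stores its 2×2 table so all four filters can be re-validated
from the object, which the test suite does.

**Fisher's exact test** sums the hypergeometric probabilities of all
tables (margins fixed) at most as probable as the observed one. For grand
totals ≤ 2000 this is done in exact integer arithmetic (numerators share
the denominator C(n, k), so ties are decided exactly); larger tables use a
vectorized log-pmf sum with the customary 1e-7 relative tie tolerance. A
zero row or column margin yields p = 1 by convention.

## DMR annotation

A DMR matches a feature when ≥ 50 % of the *DMR's* length overlaps that
single feature (overlaps with different features are not summed). The
grammatically ambiguous TE case is read in parallel with the gene clauses:
50 % of the DMR, not 50 % of the TE. Promoters are the 200 bp immediately
upstream of the first exon on the gene's strand, clipped at chromosome
ends; when both a promoter and a gene body reach 50 % the promoter wins,
so the two columns stay disjoint in tables. A DMR matching both a gene
element and a TE (e.g. a TE inside an intron) falls into the combined
category; in the summary table that category has its own column *and* its
members are also tallied inside the gene-element and TE columns, which is
why the overlapping column percentages exceed 100 by exactly the combined
share. "Other" means no ≥ 50 % match of any kind, regardless of smaller
partial overlaps.

Superfamily summaries count *distinct* TEs targeted; family
representation reports families whose targeted fraction strictly exceeds
the threshold (default 10 %). Cross-genotype overlaps are decomposed into
disjoint Venn cells over feature-id sets; unique fractions are formatted
as `NN.NN% (unique/total)`.

## Replicate QC

Samples are compared over the CG sites covered (≥ 1 read by default) in
every methylome, as per-site frequencies. The PCA centers each site but
does not scale — frequencies already share the [0, 1] scale — and uses the
deterministic full-SVD solver; each component's sign is fixed by making
its largest-magnitude loading positive.

## Synthetic data

The generator states a small world: one chromosome; genes (1–4 kb) and
TEs (bimodal: short 200–800 nt, long 3–8 kb) placed uniformly without
overlap; TE families drawn within superfamilies at configurable weights.
Per compartment and context a baseline level applies — defaults TE
CG 0.85 / CHG 0.55 / CHH 0.10, gene-body CG 0.25, background near zero —
mimicking the qualitative plant ordering (high TE CG/CHG, low CHH, CG
gene-body methylation). Cytosine positions are placed at context-specific
densities (CG 0.04, CHG 0.03, CHH 0.20 per nt, both strands pooled — CHH
dense enough that a 200-nt region holds ~40 sites, comfortably above the
20-site filter at realistic coverage). Coverage is Poisson (default mean
20); methylated counts are beta-binomial with intra-class correlation
`dispersion` (default 0.02, a mild replicate overdispersion; 0 gives pure
binomial — the moment-recovery tests use 0 so binomial standard deviations
are the right yardstick).

Planted DMRs are pairwise disjoint, each inside a single compartment
(TEs with probability `te_fraction`, default 0.8, else intergenic), with a
signed level shift drawn from `effect_range` (default magnitude 0.3–0.5).
When a compartment baseline cannot absorb the requested direction without
leaving [0, 1] — e.g. a −0.3 shift on a 0.10 CHH baseline — the direction
is flipped rather than clipped, so the realized |effect| always equals the
requested magnitude. Under the default baselines this makes planted CHH
DMRs hypermethylated, which is also a biologically attested regime: some
RdDM mutants gain CHH methylation at many loci. Raising the TE CHH
baseline in a custom model produces hypomethylated plantings instead.

One scenario seed fans out into independent child streams (feature
placement, cytosine landscape, planting, and each genotype × replicate
count draw), so replicates and genotypes share cytosine positions — as
real methylomes of one genome do — and regeneration of any stage is
deterministic and byte-stable.

**What a green synthetic test does and does not establish.** The
generator emulates compartment structure, coverage noise, replicate
overdispersion and localized differential regions. It does not emulate
mappability gaps, bisulfite non-conversion, strand- or position-dependent
coverage bias, chromosomal methylation gradients (pericentromeric
enrichment), or partially overlapping real annotations. Recovery results
(sensitivity ≥ 0.9, FDP ≤ 0.1 on the reference scenario) therefore
validate the caller's logic at the stated effect sizes and coverage, not
its performance on any particular real methylome.

## Numerical conventions and degenerate inputs

- Missing levels are NaN everywhere; comparisons propagate NaN and
  summaries skip it.
- Level-difference thresholds are applied with a 1e-12 slack so exact
  boundary cases (a difference of exactly 0.10) pass as "at least".
- Promoters at chromosome edges are clipped, not rejected; an empty
  clipped promoter is dropped.
- Unsorted CX input is sorted on load with a logged notice; duplicate
  (chrom, pos, strand) keys, unknown context tokens and non-integer
  counts are errors naming the offending line.
- BED scores are `round(-10·log10 p)` capped at 1000 (p = 0 maps to the
  cap).
- Interval queries use per-chromosome vectorized start/end arrays —
  feature counts here are small enough that an indexed tree buys nothing.
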