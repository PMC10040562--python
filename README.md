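# methyldmr

Analysis toolkit for whole-genome bisulfite sequencing (WGBS) methylomes in
plants, built around the comparison of a wild-type and a mutant methylome —
for example RNA-directed DNA methylation (RdDM) pathway mutants such as
*ago4*, *ago9* or *rdr6* in *Arabidopsis*. It covers the full downstream
path from per-cytosine methylation calls to differentially methylated
regions (DMRs) and their genomic annotation:

- **Methylation levels** per cytosine, per 50-nt bin, and genome-wide, in
  the three plant sequence contexts (CG, CHG, CHH). All aggregation uses
  the *weighted* level — total methylated reads over total reads,
  mC / (mC + C→T) — never the mean of per-site frequencies.
- **Metaprofiles**: average methylation around the 5′ or 3′ end of genes
  and transposable elements (TEs), pooled into 100-bp intervals over ±5 kb,
  with positions near the opposite feature end masked (1500 bp for genes,
  250 bp for TEs).
- **DMR calling**: 50-nt windows where the pooled level difference reaches
  a context-specific threshold (CHH ≥ 10 %, CHG ≥ 20 %, CG ≥ 40 %) are
  merged when ≤ 100 nt apart; merged regions are kept when ≥ 100 nt long
  with ≥ 20 cytosine sites, re-passing the threshold, and significant by
  a two-sided Fisher's exact test (p < 0.001) on the pooled 2×2 count
  table (wt meth/unmeth vs mutant meth/unmeth).
- **Annotation**: a DMR maps to a promoter (200 bp upstream of the first
  exon), gene body (first through last exon) or TE when ≥ 50 % of its
  length overlaps the feature; summaries by category, TE superfamily and
  family, and Venn-style overlaps of targeted features across genotypes.
- **Replicate QC**: PCA of samples over the CG sites covered in every
  methylome.
- **Synthetic methylomes**: a generator with compartment-specific baseline
  levels (TE vs gene body vs intergenic), Poisson coverage, beta-binomial
  counts and *planted* DMRs of known coordinates and effect sizes, so every
  stage of the pipeline can be scored against ground truth.

Inputs are Bismark cytosine/CX reports (one row per cytosine: chromosome,
1-based position, strand, methylated count, unmethylated count, context,
trinucleotide), GFF3 gene models, and TAIR10-style TE tables; DMRs are
written as BED6+ plus a full TSV. All readers accept gzip input.

## Worked example

Simulate a scenario (1 Mb genome, 40 genes, 80 TEs, two replicates per
genotype at 20× coverage, 60 planted CHH DMRs with |effect| ≥ 0.3), call
CHH DMRs, and annotate them:

```bash
methyldmr simulate --out demo --seed 3
methyldmr dmr --wt demo/wild-type_R1.cx.gz --wt demo/wild-type_R2.cx.gz \
              --mut demo/mutant_R1.cx.gz --mut demo/mutant_R2.cx.gz \
              --context CHH -o demo/dmrs.bed
# 59 CHH DMRs written to demo/dmrs.bed
head -3 demo/dmrs.bed
# chr1  14200  14550  CHH:hyper  1000  .  0.0208  0.4123  68
# chr1  24500  24750  CHH:hyper  1000  .  0.0187  0.3357  46
# chr1  31300  31550  CHH:hyper  1000  .  0.0987  0.4757  48
methyldmr annotate --dmrs demo/dmrs.tsv --gff demo/genes.gff3 \
                   --te demo/tes.tsv -o demo/assignments.tsv
```

Each BED line is one DMR: the name carries context and direction (mutant
relative to wild-type), the score is `round(-10·log10 p)` capped at 1000,
and the extra columns are the pooled wild-type level, mutant level and the
number of cytosine sites covered in both genotypes. Here the first DMR
rises from 2.1 % to 41.2 % CHH methylation over 68 sites — a planted
hypermethylated region recovered by the caller. The annotate step prints a
category table (promoter / gene body / TE / combined / other with
percentages); in this scenario 78 % of CHH DMRs map to TEs, mirroring how
DMRs concentrate in transposons when methylation of TEs is perturbed.

The same operations are available as library functions
(`methyldmr.call_dmrs`, `methyldmr.assign_dmrs`,
`methyldmr.compute_metaprofile`, …); see the docstrings and
`docs/methods.md`.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the full pipeline from scratch on the seeded reference
scenario: global levels of the pooled wild-type, DMR calls in all three
contexts, the CHH category table, recovery of the planted DMRs
(sensitivity and false-discovery proportion against ground truth), and
the replicate PCA, printing each summary and writing the results JSON.
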