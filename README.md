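# ssrscout

Gene-anchored microsatellite (SSR) marker discovery for defense- and
resistance-associated loci, with permutation-based density hotspot calling,
random-forest candidate prioritization, primer design, and multi-genome
in silico PCR.

`ssrscout` is aimed at plant breeders and molecular geneticists who need
co-dominant SSR markers tightly linked to candidate genes — e.g. pathogen-
and pest-response gene families such as WRKY, NAC, LRR, peroxidase (PRX)
and chitinase (CHI) — rather than genome-wide marker sets. Instead of
mining SSRs everywhere and filtering afterwards, the workflow starts from
a list of target gene loci, asks where SSRs cluster *around those genes*
more than chance allows, and only develops markers from those statistically
supported putative-QTL (pQTL) hotspot regions.

## The method

**SSR mining.** For each target locus the region gene ± 5 kb is scanned for
perfect tandem repeats with motif length *k* ∈ [2, 6] bp, requiring ≥ 8
copies for *k* = 2, ≥ 5 for *k* = 3, ≥ 4 for *k* = 4 and ≥ 3 for *k* = 5–6.
Runs are maximal, never cross N, and each repeat tract is reported once at
its minimal period.

**Hotspot statistics.** The region is tiled with 1-kb windows at offsets 0
and 500 bp (pooled, half-overlapping). With per-window counts *x*, locus
mean µ and sample standard deviation σ, each window gets a density Z-score
*z* = (*x* − µ)/σ. The null is locus-specific: the observed SSR count is
redistributed uniformly over the region B = 1000 times and the maximum
window Z of each permutation is recorded; the empirical 95th/99th
percentiles of this max-Z distribution are the significance thresholds.
Windows whose observed *z* strictly exceeds a threshold are merged into
hotspot regions.

**Selection.** Candidates are restricted to SSRs overlapping 99%-level
hotspots (falling back to 95% when a locus would otherwise be empty),
ranked by repeat count, then proximity to the gene, capped at 100 per
locus. A structural filter (≥ 8 copies for 2–4-bp motifs, ≥ 4 for 5–6-bp
motifs) precedes the final panel of at most five markers per locus.

**Random-forest prioritization.** Within each protein family, SSRs in
99%-level hotspots form the positive class and SSRs in hotspots that never
reach 99% the negative class. A 1000-tree random forest (three variables
per split, probability output, impurity importances) is fit on a
stratified 70/30 split, and candidates with P(positive) ≥ 0.70 are ranked
by probability, repeats and distance. An ablation compares the positive
rate (selected positives / selected) of this strategy against the
heuristic baseline; the difference is the uplift.

**Primers and e-PCR.** Primer pairs are designed over the SSR ± 200 bp
(length 18–25 nt, Tm 50–65 °C, GC 35–65 %, product 100–400 bp spanning the
repeat). Each pair is screened across genome assemblies by exact-match
electronic PCR (0 mismatches, both orientation combinations, products
≤ 1000 bp), and cross-genome polymorphism is scored with Botstein's
polymorphic information content,
PIC = 1 − Σ pᵢ² − Σᵢ<ⱼ 2 pᵢ² pⱼ², from the observed amplicon lengths;
PIC > 0.5 marks highly informative markers.

A synthetic-data module generates multi-contig genomes with annotated
genes, planted SSR arrays (clustered or scattered), jittered "cultivar"
derivatives and proteomes with planted family motifs — all with exact
truth tables — so the entire pipeline is testable without downloads.

## Worked example

Simulate a study and run the pipeline end to end:

```bash
ssrscout simulate --seed 2 --out demo --cultivars 2
ssrscout run-all --config demo/config.yaml --out demo/run
```

with `demo/config.yaml`:

```yaml
reference_fasta: demo/reference.fasta
locus_table: demo/loci.tsv
gff: demo/annotation.gff3
cultivar_fastas:
  cultivar1: demo/cultivar1.fasta
  cultivar2: demo/cultivar2.fasta
seed: 2
```

The run report prints:

```json
{
  "version": "0.1.0",
  "seed": 2,
  "n_loci": 9,
  "n_ssrs_mined": 162,
  "n_hotspot_regions": 18,
  "n_loci_in_panel": 9,
  "n_panel_ssrs": 45,
  "n_primer_pairs": 45,
  "n_polymorphic_primers": 43,
  "families_with_rf": []
}
```

162 SSRs were mined around the nine target genes; every locus produced a
99%-level hotspot, the panel kept the best five markers per locus (45),
one primer pair was designed per panel SSR, and 43 of the 45 pairs are
polymorphic (PIC > 0) across the reference plus two jittered cultivars.
`demo/run/final_panel.tsv` holds the marker table — for example

```
locus_id  gene_label  family_tag  contig   start  end   motif  k  repeats  distance  region_class       hotspot_level  max_z
g001      CsG001      WRKY        contig1  4753   4776  AT     2  12       1354      promoter_upstream  99             3.40
```

and `demo/run/pic_summary.tsv` the cross-genome polymorphism, e.g. primer
AE001 amplifying alleles 229/236/240 bp in the three genomes
(PIC = 0.593, above the 0.5 informativeness bar).

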