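# Methods

This note documents the models and numerical choices behind `ssrscout`,
what the synthetic-data generator does and does not emulate, and the known
limitations of the approach.

## Coordinates and sequence handling

All coordinates are 1-based inclusive, following the GFF convention of the
annotation inputs. Nucleotide sequences are uppercased on load and any
IUPAC ambiguity symbol other than N is mapped to N with a logged warning;
N never matches anything (SSR runs cannot cross it, primers containing or
spanning it never bind). Analysis regions are the locus ± `flank`
(default 5000 bp), trimmed to `[1, contig_length]`.

## SSR detection

A tandem repeat is reported when a *primitive* motif (not itself a
repetition of a shorter motif) of length k ∈ [2, 6] occurs consecutively
at least threshold(k) times: 8, 5, 4, 3, 3 for k = 2…6. Two rules make
the output unambiguous:

- **Per-base maximality.** A run is maximal when it cannot be extended by
  a single base continuing its periodicity (seq[i−1] ≠ seq[i−1+k] on the
  left, symmetrically on the right). This is slightly stronger than
  "not extendable by a whole motif copy" and is what makes reporting
  unique: rotated sub-runs (CA×8 inside AC×9) and whole-copy-shifted
  sub-runs are all left-extendable by one base and therefore suppressed.
  Runs with a trailing partial copy are truncated to whole copies,
  anchored at the left edge.
- **Minimal period.** Primitivity of the motif guarantees a tract is
  reported once: AT×8 is not additionally reported as ATAT×4.

Detection scans the + strand only; a perfect tandem repeat exists
equivalently on both strands, so the record's strand field carries the
owning locus's strand. `ssrscout.oracles.enumerate_ssrs_bruteforce`
implements the same mathematical rule by exhaustive per-start string
comparison and serves as the independent reference in tests; the two
routes agree exactly on thousands of random and adversarial sequences.

One edge case is documented rather than "fixed": two maximal runs of the
same period can share up to k − 1 bases at a junction such as
`ACACACACACACACAC|GCGCGCGCGCGCGCG` (the shared C belongs to both). The
no-overlap property is therefore asserted as overlap < k, not zero.

## Window grid, Z-scores and the permutation null

Windows of `window_size` (default 1000 bp) are laid at offsets 0 and
500 bp and pooled into one grid; trailing windows are trimmed, kept, and
counted without width normalization. An SSR belongs to every window whose
span contains its start coordinate (a start on a shared boundary counts
in both offset grids). Zero-count windows are retained, so the locus mean
µ and standard deviation σ are over the complete pooled grid; σ uses the
sample (n − 1) denominator. z = (x − µ)/σ is undefined when σ = 0, and
such loci (or loci without SSRs) are excluded from permutation analysis
with a log entry rather than an exception.

The null redistributes the observed SSR count uniformly and independently
(with replacement) over region base positions B = 1000 times, projects
each permutation onto the same grid, standardizes with the *observed*
µ and σ, and records the per-permutation maximum window z. Thresholds are
empirical order statistics at rank ⌈p·B⌉ of the sorted max-Z sample
(p = 0.95, 0.99); "significant" means strictly greater. Significant
windows that overlap or are bookended merge into hotspot regions carrying
their window count and maximum z.

### Calibration and discreteness

Because µ and σ are locus constants, max-Z is a monotone function of the
integer maximum window count, so the null distribution is concentrated on
a handful of atoms. Two consequences, both visible in the test suite and
the acceptance summary:

- With strict exceedance, the realized false-positive rate sits at or
  below the nominal level (for a continuous statistic it would be
  (B + 1 − ⌈pB⌉)/(B + 1) ≈ 0.011 and 0.051). Ties depress it further, most
  severely at low SSR counts. The calibration simulation uses 200 null
  loci with 20–80 SSRs each (1–6 starts per kb — moderate densities,
  consistent with the 100-candidate-per-locus ranking cap) where the
  attenuation is mild; the observed rates are checked against the exact
  central 99% binomial band around 1% and 5%.
- The 95% and 99% thresholds frequently coincide in count units (the
  950th and 990th order statistics fall on the same atom). Then no SSR
  can be "significant at 95% but not 99%", which is why the negative
  class of the random-forest stage is structurally rare on synthetic
  data (see below).

### Power

Parameter recovery is measured by planting a 3-fold elevation of the SSR
start rate in one 1-kb tile (baseline Poisson(2.5) per tile, ≥ 10 SSRs
per locus) and asking how often a 99%-level hotspot overlaps the planted
tile. The measured recall is ≈ 0.14–0.18 under these conditions; the test
floor is frozen at 0.10 (one-time choice with ≈ 3 SD of margin). A
single-window 3× bump over a noisy background is a genuinely weak signal
for a max-statistic test at the 99% level; the low absolute recall is a
property of the method, not of the implementation.

## Candidate selection

Hotspot restriction is hierarchical: 99%-level regions first; if a locus
yields no candidate, its 95%-level regions are used (flagged as such).
Ranking is by repeat count (descending — higher copy numbers mutate
faster and are more polymorphic), then minimum interval gap to the gene
body (ascending; "distance" is 0 for any overlap), then genomic start
(ascending — an explicit tie-break that makes the order total and runs
reproducible), capped at 100 per locus. The panel-stage structural filter
(≥ 8 copies for k = 2–4, ≥ 4 for k = 5–6) is deliberately stricter than
the mining thresholds; both are applied, each at its own stage. At most
five markers per locus enter the final panel.

Genomic context labels partition each SSR–locus pair: exon overlap →
`exonic`; otherwise inside the gene body → `intronic`; otherwise within
the flank on the gene's 5′ side (strand-aware) → `promoter_upstream`,
3′ side → `downstream`; beyond the flank → `distal_intergenic`.

## Random-forest prioritization

Labels: positive = overlaps a 99%-level hotspot; negative = overlaps a
hotspot but no 99%-level one; SSRs outside hotspots are excluded, so the
model can only re-rank candidates already inside pQTL regions, never
introduce outside ones. Features (the classifier's own design — a
reasonable structural/contextual set): motif length, repeat count, tract
length, distance to gene, motif GC fraction, hosting-window z (with a
missing-z mask flag), strand indicator. Hyperparameters: 1000 trees,
3 variables per split, probability output, impurity-based importances,
stratified 70/30 split at a fixed seed. Training requires ≥ 10 examples
per class; single-class families are skipped with a warning and flow
through the heuristic path. The trained model scores *all* family SSRs,
training items included — those scores are optimistically biased, which
is logged; the ablation compares both strategies on the same pool, so the
comparison is internally consistent.

The ablation metric is positive rate = selected positives / selected,
reported per locus and overall; uplift is the ML strategy's overall rate
minus the baseline's (repeats + distance ranking only). On data where the
classes are separable by construction, held-out accuracy ≈ 1 and the
uplift is positive; with a constant probability score, ML selection
provably reduces to the baseline (asserted as a property test).

## Primer design

No thermodynamic design engine is bundled as a dependency; the module
ships a small exhaustive picker. Candidate primers of 18–25 nt are
enumerated over both flanks of the SSR ± 200 bp template, filtered to
GC 35–65 % and Tm 50–65 °C (nearest-neighbor Tm via Biopython by default,
Wallace rule configurable), scored with a primer3-style penalty
(|Tm − 60| + 0.5·|len − 20| per primer, plus the pair's Tm difference),
and the lowest-penalty pair whose product is 100–400 bp and spans the
repeat is returned. Templates with under 50 bp of usable flank after
contig trimming are skipped (degenerate designs near contig ends).
`validate_pair` re-checks every constraint from scratch and returns a
violation list, so externally supplied primer tables can be audited with
the same rules.

## In silico PCR and PIC

Binding is exact string matching — no mismatches, no ambiguity codes.
For both orientation combinations (forward with reverse-complemented
reverse, and the converse), every upstream plus-strand site is paired
with every downstream occurrence of the other primer's reverse
complement; the product spans the upstream 5′ base through the downstream
footprint's last base and is capped at 1000 bp. A pair may legitimately
yield many amplicons; per-genome multi-product behavior is flagged.

PIC uses Botstein's formula, 1 − Σ pᵢ² − Σᵢ<ⱼ 2 pᵢ² pⱼ², with allele
frequencies taken from the pooled multiset of amplicon lengths — one
observation per predicted amplicon, across all genomes; genomes without
amplification contribute nothing. Pooling is a convention choice (an
allele-per-locus accounting would require assigning off-target amplicons
to loci); it is monotone in the intended sense: identical products
everywhere give PIC = 0, length variation gives PIC > 0, and three
equifrequent alleles give ≈ 0.593.

## Synthetic data: what it emulates, what it does not

The generator emulates the *structure* the pipeline assumes: multiple
contigs with uniform i.i.d. background (configurable GC), non-overlapping
genes with exon/intron layout, planted perfect SSR arrays whose flanking
bases are modified to break the periodicity (so planted copy numbers are
recovered exactly), a dense planted cluster within one window span per
gene (the hotspot signal, 8 arrays) plus a weaker secondary cluster and
scattered arrays, cultivar derivatives whose planted arrays are
expanded/contracted by sampled copy-number deltas with background SNPs
kept ≥ 250 bp away from planted arrays (so primer footprints stay exact
by default; raising the SNP rate into footprints emulates
cultivar-dependent amplification dropout), and random proteomes with
planted family motifs linked to genes via GFF protein ids.

It does *not* emulate real plant genomes: no genome-wide repeat
landscape, no GC heterogeneity or isochores, no imperfect/compound SSRs,
no heterozygosity or assembly artifacts, no homology between cultivars
beyond the shared simulated ancestor. Passing tests therefore demonstrate
that the statistics, bookkeeping and truth-recovery are correct under the
model's assumptions — not that real-genome marker yields will match any
particular published count.

Chance background runs passing the mining thresholds occur at roughly
1 per Mb of uniform sequence; truth tests therefore assert recall = 1
against planted arrays and *set equality against the exhaustive
enumerator* for precision, rather than assuming planted arrays are the
only SSRs present.

## Determinism

Every stochastic component takes a seed or a `numpy` Generator; per-locus
permutation streams are derived from (run seed, locus index). Reruns with
the same inputs, config and seed produce byte-identical tables; each
output table carries a header comment with the package version, seed and
a config hash.

## Problem sizes

Defaults were chosen so the full test suite and the acceptance script
each complete in well under typical CI budgets: the shared synthetic
study uses 9 genes on 3 × 100 kb contigs; the acceptance study 30 genes
on 10 contigs with 3 cultivars; calibration and power simulations use 200
loci at B = 1000. All sizes are parameters, and all scale linearly.

## Known limitations

- Strand assignment of SSRs is a convention (locus strand), since a
  double-stranded tandem repeat has no intrinsic orientation.
- The strict-exceedance permutation test is conservative on tied,
  discrete max-count nulls (quantified above).
- RF probabilities are not calibrated; the 0.70 cutoff is a rank
  threshold, not a posterior probability with frequency guarantees.
- e-PCR is purely combinatorial: no mismatch tolerance, no thermodynamic
  binding model, no primer-dimer or secondary-structure checks beyond the
  design-stage constraints.
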