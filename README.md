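# regutarget

**ChIP-seq × differential-expression integration: from binding sites to a
phenotype-predictive direct-target signature.**

`regutarget` implements, as a tested and reusable pipeline, the analysis a
transcription-factor perturbation study uses to answer three questions:

1. **Where does the factor bind?** Peak calls from two independent callers
   are reduced to a *consensus* set — the merged pairwise interval
   intersections, so every consensus base pair is supported by both
   callers. Each consensus peak is annotated with a genomic category
   (promoter ≤ 1 kb, 5′/3′ UTR, CDS exon, intron, promoter 1–10 kb,
   downstream ≤ 10 kb, distal intergenic) and a signed distance to the
   nearest transcription start site (TSS), positive downstream in gene
   orientation.

2. **Does binding change expression?** The *distance–response curve* bins
   peaks by |distance to nearest TSS| and compares the mean |log₂ fold
   change| of the nearest genes per bin against a permutation null band
   (expression values randomly re-assigned to genes, pointwise
   percentiles). *Direct targets* are genes with a consensus peak within
   `D_max` = 10 kb of the TSS whose expression passes |FC| ≥ 1.5 at
   FDR ≤ 0.25 — the direct transcriptional signature.

3. **Does the signature carry phenotype?** Enrichment of the signature is
   scored two ways — exact upper-tail hypergeometric overlap tests with
   odds ratios against an explicit gene universe, and preranked GSEA
   (weighted running-sum enrichment score, gene-sampling permutation null,
   sign-matched NES, ratio-of-tails FDR) with an enrichment-map graph of
   the significant sets — and the signature is evaluated as a
   molecular-subtype classifier (diagonal LDA or Gaussian naive Bayes)
   under 100 iterations of stratified 10-fold cross-validation, reporting
   per-iteration misclassification rates and a percent confusion matrix.

A first-class synthetic-data module generates gene annotations, paired
noisy caller views of one underlying peak set, distance-decaying
differential-expression tables, gene-set collections and subtype-structured
cohorts — all with planted ground truth and full seed determinism — so the
entire pipeline is testable end to end without any external download.

## The statistics at the core

* Hypergeometric overlap of sets A, B in a universe of size N:
  `p = Σ_{j≥k} C(K,j)·C(N−K,n−j)/C(N,n)`, computed with exact integer
  arithmetic (published overlaps reach p ~ 1e-80, beyond float tail sums);
  odds ratio `(a·d)/(b·c)` with Haldane–Anscombe +0.5 when a cell is 0.
  The universe is a required, echoed argument — it is the single most
  influential parameter of such tests.
* GSEA enrichment score: running sum gaining `|s_i|^p / N_R` at set members
  and losing `1/(N−N_H)` at non-members; ES is the extremum of largest
  magnitude, the leading edge the members at or before it (after it for
  negative ES). NES divides ES by the mean |null ES| of matching sign from
  same-size random gene draws; FDR q is the GSEA ratio-of-tails statistic.
* DLDA assigns `argmin_c Σ_j (x_j − μ̂_cj)²/s_j²` with pooled per-gene
  variances; with equal priors and class-shared variances Gaussian naive
  Bayes reduces to the same rule.

## Worked example

```python
import regutarget as rt

chrom_lengths = {"chr1": 200_000_000}
genes = rt.simulate_genome(2_000, [200_000_000], seed=7)
peaks_a, peaks_b, truth = rt.simulate_chip_peaks(genes, chrom_lengths, seed=8)
consensus = rt.intersect_peak_sets(peaks_a, peaks_b)

de = rt.simulate_de_table(genes, truth, seed=9)
table, signature = rt.call_direct_targets(consensus, genes, de)

sets = rt.simulate_gene_sets(genes, truth, n_sets=30, set_size=100,
                             enrichment=0.7, seed=10)
universe = [g.gene_id for g in genes]
overlap, res = rt.intersect_with_set(signature, sets["PLANTED_TARGETS"], universe)

mat, labels = rt.simulate_cohort(sorted(signature)[:40], n_other=200,
                                 subtype_sizes=(20, 20, 20), seed=11)
report = rt.cross_validate(mat, labels, sorted(signature)[:40],
                           classifier="dlda", k=10, iterations=100, seed=12)
```

prints (via the obvious `print` calls):

```
399 consensus peaks from 400 + 400 caller peaks
193 direct targets called; precision 0.995, recall 0.960
overlap with planted set: k=70 of K=193, p = 6.7e-53, OR = 33.7
median CV misclassification: 0.000
predicted  subtype_1  subtype_2  subtype_3
true
subtype_1      100.0        0.0        0.0
subtype_2        0.0      100.0        0.0
subtype_3        0.0        0.0      100.0
```

399 of the 400 underlying peaks survive the two-caller consensus (two
overlapping peaks merged); the threshold rule recovers the planted targets
at 0.995 precision / 0.960 recall; their overlap with the planted gene set
is astronomically unlikely under the hypergeometric null; and the
target-derived signature classifies the simulated subtypes without error.

The same pipeline is scriptable from the shell:

```bash
regutarget simulate --outdir sim --seed 5
regutarget intersect-peaks sim/peaks_A.bed sim/peaks_B.bed -o consensus.bed
regutarget annotate consensus.bed sim/genes.bed12 -o annot.tsv
regutarget distance-curve consensus.bed sim/genes.bed12 sim/de_table.tsv -o curve.tsv
regutarget call-targets consensus.bed sim/genes.bed12 sim/de_table.tsv -o targets.tsv
regutarget gsea ranked.tsv sim/gene_sets.gmt --nperm 1000 --seed 3 -o gsea.tsv
regutarget enrichment-map gsea.tsv sim/gene_sets.gmt -o map.graphml
regutarget classify cohort.tsv labels.tsv --signature sig.txt -o report.json
```

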