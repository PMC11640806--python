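# Methods

This note documents the models, statistics and design choices behind
`lncflow`, and what the synthetic-data tests do and do not demonstrate.

## Transcript triage

Transcripts are represented with 1-based closed exon intervals (the GTF
convention); conversions happen only at I/O boundaries. The triage
cascade applies three filters in order:

1. **Class codes.** Only transcripts whose gffcompare class code is in
   `{x, o, i, u, j}` are retained — the codes compatible with a novel
   transcript (antisense-exonic, other-strand overlap, intronic,
   intergenic, novel isoform). Codes outside the known gffcompare
   alphabet trigger a warning and the transcript is dropped.
2. **Structure.** Length ≥ 200 nt and ≥ 2 exons (both boundaries
   inclusive). Short or mono-exonic assemblies are enriched for
   artifacts, and 200 nt is the defining lncRNA length floor.
3. **Longest ORF.** The scanner walks codons in the three forward frames
   only (assembled transcripts are already stranded) and tracks maximal
   ATG→stop runs. ORF length counts ATG through the last codon before
   the stop; the stop codon is excluded, so 100 aa ⇔ 300 nt. A codon
   containing N terminates the current run (the truncated run is still
   reported, without a stop), as does the end of the sequence. Ties are
   broken by smallest start offset, then smallest frame. The default
   filter mode `drop_long` removes transcripts whose longest ORF is
   ≥ 300 nt — the standard direction for lncRNA discovery (long-ORF
   transcripts are presumed coding). The inverse rule is available as
   `drop_short` for pipelines that want to keep ORF-bearing transcripts.

The scanner is verified against an exhaustive O(L²) (start, frame)
oracle; the filters are verified against independent set logic at the
199/200 nt, 1/2 exon and 297/300 nt boundaries.

## Coding-potential classifier

Training sequences are deduplicated exactly (identical nucleotide
sequences collapse to the first record; a sequence appearing under both
labels is contradictory and removed entirely). Features per sequence:

- longest-ORF length (nt) and ORF coverage (ORF length / transcript
  length);
- GC fraction;
- Fickett TESTCODE statistic, using the classic published
  position-asymmetry and composition lookup tables;
- hexamer usage log-ratio: mean over the sequence's overlapping hexamers
  of log(f_coding / f_noncoding), with both tables estimated from the
  training corpus with add-one smoothing over all 4,096 hexamers;
- normalized k-mer spectra for k = 1, 2, 3 (each block sums to 1).

The classifier is a random forest (500 trees, √p features per split) with
tree depth tuned over {None, 10, 20}; model selection and the reported
per-fold precision/recall/accuracy use stratified 10-fold
cross-validation, and the final model is refit on all training data.
**Leakage control:** the hexamer table is label-derived, so it is
re-estimated inside each fold from that fold's training records only.
Fitting it once on the full corpus leaks held-out sequences into the
feature and drives a label-permutation control from chance (~0.50) to
~0.94 apparent accuracy; the permutation control is part of the test
suite precisely to pin this down. The positive class for
precision/recall is *noncoding*, the class the pipeline retains.

## Homology triage

A hit is significant iff E ≤ 1e-5 (inclusive; the comparator is tested at
the boundary). When a candidate has significant hits of several subject
types, coding/non-lncRNA evidence dominates (conservative exclusion),
then lncRNA evidence; candidates with neither form the no-match group.
Groups always partition the candidate set, and tightening the threshold
can only move candidates toward the no-match group. Subject types are an
input column: how subjects map to protein-coding / non-lncRNA / lncRNA
is externalized to whoever produced the hit table.

## Differential expression

The engine re-implements the standard NB machinery rather than wrapping
an existing package:

- **Size factors** by median-of-ratios over features with all-positive
  counts. The median is taken in log space (`exp(median(log ratios))`),
  which matches DESeq2/pydeseq2 exactly (verified to 1e-8 in the tests);
  it differs from a linear median only at even feature counts, where the
  two middle ratios are interpolated geometrically rather than
  arithmetically.
- **Dispersion** per feature by method-of-moments on normalized counts
  (pooled within-group variance), floored at 1e-8, then shrunk halfway
  toward a least-squares trend `α(μ) = a₀ + a₁/μ` (coefficients clipped
  at 0). This is a deliberate simplification of empirical-Bayes
  dispersion shrinkage that keeps the estimator fully transparent.
- **Fold change** `log2((mean_contrast + 0.5) / (mean_reference + 0.5))`
  on normalized counts; the 0.5 pseudo-count shrinks zero-group fold
  changes toward 0 instead of producing infinities.
- **Wald test**: the standard error of the log2 fold change comes from
  the delta method with per-sample NB variance `μ/s_i + αμ²` evaluated at
  the pseudo-counted group means; the statistic is referred to a normal
  distribution. Measured null calibration at the simulation conditions
  used throughout (μ = 100, α = 0.05, n = 4 + 4): type-I error ≈ 0.052
  at nominal 0.05, so no small-sample t-correction is applied.
- **BH adjustment** is a hand-written step-up with monotonicity
  enforcement, tested against statsmodels on random vectors.
- **DE call**: adjusted p < 0.05 (strict) and |log2FC| ≥ 1 (non-strict),
  annotated up/down by the sign of the fold change, split into DELs
  (lncRNA features) and DEGs (mRNA features). All-zero features are
  flagged with p = 1 and log2FC = 0.

Sample similarity uses log2(normalized + 1) expression: PCA by SVD of the
column-centered sample matrix, plus a Euclidean distance matrix. The
structural comparison reports per-class mean ± SEM of transcript length,
mean exon length and exon number, with length bins <1500 / 1500–3000 /
>3000 nt and exon bins 2–3 / 4–10 / >10; singleton classes report SEM 0
with a `sem_defined = False` flag.

## Target inference

Correlations are computed on log2(normalized count + 1) across **all**
samples, both groups pooled — co-expression in the usual sense. The
p-value uses `t = r·√((n−2)/(1−r²))` on n−2 df; |r| = 1 maps to p = 0
exactly. Pairs are retained at |r| ≥ 0.90 and p < 0.01. The correlation
magnitude threshold is interpreted as a bound on the *signed* Pearson
coefficient's absolute value (a squared coefficient cannot be negative,
and negative correlations are meaningful here). The p threshold default
is 0.01, configurable to 0.05.

Genomic distance is the gap in bp between transcript *spans* (first exon
start to last exon end), 0 when the spans overlap, strand ignored, and
undefined across chromosomes. A retained pair is cis iff same chromosome
and gap < 20,000 (strict; 19,999 is cis, 20,000 is trans); all other
retained pairs are trans. Correlation screening runs before the distance
screen, so the cis set is a subset of the correlation-passing pairs. A
DEL with at least one cis and one trans pair is reported as dual-mode.

## Enrichment

The upper-tail hypergeometric probability P(X ≥ k) is computed as a
log-space sum of point masses (log-gamma binomials + logsumexp) and
verified against exhaustive enumeration for every feasible (k, K, n, N)
with N ≤ 60. The universe is the term map's annotated gene set,
optionally intersected with the expressed genes (the pipeline passes the
count-matrix features). Terms smaller than 3 genes in the universe are
not tested. Enrichment uses a non-strict cutoff (adjusted p ≤ 0.05),
deliberately different from the strict DE cutoff. The term map is an
input file; real GO/KEGG term counts are therefore outside what this
package can reproduce.

## Synthetic data: what it emulates, and what it does not

The generator mirrors the statistical structure the analysis stages
assume, with two groups × 4 replicates as the default design:

- **Annotation**: reference genes (3–12 exons of 120–400 nt) laid out
  with ≥ 20 kb intergenic gaps; novel transcripts draw class codes from a
  mix dominated by intergenic "u" (novel lncRNAs are predominantly
  intergenic); a 10% fraction deliberately fails the structural filters.
  Planted cis lncRNAs are placed with a span gap < 20 kb from their
  partner gene (the gene spacing guarantees no interference); planted
  trans lncRNAs go to a different chromosome.
- **Sequences**: coding-truth transcripts carry an in-frame ORF ≥ 300 nt
  sampled from a synthetic GC-biased codon table; noncoding-truth
  transcripts are AT-biased i.i.d. sequences whose rare long ORFs are
  destroyed by mutating their start codons. The two classes therefore
  differ in ORF structure, GC, and hexamer composition — separable by
  design, which is what makes exact recovery testable.
- **Counts**: NB with dispersion α = 0.05 (typical bulk RNA-seq);
  baseline means log-uniform in [20, 500]; planted log2 fold changes are
  split symmetrically between the groups. Planted pairs share a Gaussian
  latent factor (SD 1.0 on the log2 scale) added to both members' log
  means, sign-flipped for negative pairs; pair members carry |log2FC| = 3
  with opposite-sign fold changes for negative pairs, so the pooled-
  sample group effect reinforces rather than cancels the planted
  correlation. Together these give an expected |r| ≈ 0.95 on
  log-normalized counts and comfortably detectable DE.
- **Hit table / term map**: constructed to realize all three homology
  groups exactly and to concentrate planted target genes in two terms.

Limitations: sequencing depth, gene length bias, batch effects,
multimapping ambiguity, isoform-level quantification noise and real
codon/hexamer statistics are not modeled. Passing the planted-truth tests
demonstrates that the *algorithms* implement their contracts exactly and
that the statistics are calibrated under their own model assumptions — it
does not certify performance on real libraries, where dispersion trends,
annotation errors and homology-database coverage dominate.

Problem sizes used by the test suite and the acceptance script — 400
training sequences, 150 novel transcripts, 2,000 features × 20 simulation
replicates for DE calibration, all hypergeometric tuples to N = 60 — were
chosen to make the checks statistically meaningful while keeping a full
run in the minutes range on a single CPU.

## Numerical conventions

- Coordinates 1-based closed; span gap = `start₂ − end₁ − 1`.
- ORF ties: smallest start offset, then smallest frame.
- Dispersion clipped to [1e-8, 10].
- BH implemented with a stable mergesort so equal p-values keep input
  order.
- All generators take independent deterministic RNG substreams derived
  from `(seed, stage)`, so stage outputs are reproducible independently
  and identical seeds give byte-identical files.
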