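# Methods

`tecre` implements the computational core of TE-centric regulatory
genomics: quantifying transposable-element (TE) subfamily expression
under explicit filtering and normalization rules, inferring
per-subfamily *cis*-regulatory activity from gene-expression
deviations, and measuring TE-subfamily enrichment in
chromatin-accessibility peak sets. Everything is exercised end-to-end
on seeded synthetic genomes with planted ground truth.

## Coordinates and annotations (`genome_io`)

All coordinates are 0-based half-open internally; GTF (1-based,
inclusive) is converted on read and write, BED is native. A gene's TSS
is the 5' end of its model: `start` on the + strand, `end - 1` on the
− strand. Overlap is strand-agnostic throughout — the regulatory model
is distance-based, not strand-based.

ERV proviruses are commonly annotated as separate fragments (5'LTR,
internal segment, 3'LTR). `merge_fragmented_integrants` joins adjacent
fragments on the same chromosome and strand when their subfamilies
form a declared internal/LTR pairing (an explicit mapping such as
`{"HERVK-int": "LTR5Hs"}` — this pairing table is an input, not
guessed) and the gap is at most `max_gap` (default 100 bp, chosen
small because LTR/internal fragments of one integrant are essentially
contiguous; configurable). Merged spans take the LTR subfamily label
and keep the child locus ids; the operation is idempotent.

The shared overlap engine is vectorized numpy. For a query window
`[ws, we)` against a set of intervals whose starts and ends are each
sorted independently, the number of intersecting intervals is exactly
`#(start < we) − #(end <= ws)`; this identity holds for arbitrary
interval sets and backs both the occurrence matrix and the peak
counting. Tests compare every counting path against a brute-force
all-pairs double loop.

## Bulk quantification (`te_expression`)

Filters, applied to the joint gene + TE-locus count matrix:

* TE loci overlapping any exon by ≥ 1 bp are discarded (ambiguous
  with transcription of the host gene);
* any feature lacking at least one sample with ≥ 3 reads is discarded.
  The boundary is inclusive: counts (0,0,3) survive, (2,2,2) do not.
  The two rules commute.

Normalization is trimmed-mean-of-M-values (TMM) computed **on gene
features only**, with the per-sample sum of gene counts as the library
size — TE counts are deliberately excluded from the scaling so that
global TE activation cannot suppress its own signal. The
implementation trims 30% of M values and 5% of A values (doubly
trimmed ranks), weights the surviving M values by inverse delta-method
variances, and rescales factors to geometric mean 1. On a 1000-gene
fixture with a 5% asymmetric spike-in, factors agree with
`edgeR::calcNormFactors(method="TMM")` to < 1e-6 relative (frozen
reference in the test suite; the acceptance tolerance is 2%).

Differential expression uses a two-sided Welch t-test on
`log2(count / effective_library * scale + 0.5)` values. Moderated
(empirical-Bayes / precision-weighted) inference is intentionally not
reimplemented; the inferential scheme — log fold change, t-type
p-value, Benjamini–Hochberg correction — is preserved, and the
substitution is the package's stated approximation. A feature is
"differentially expressed" when fold change > 2 **and** raw p < 0.05;
since adjusted p < 0.05 is the convention used for subfamily-level
summaries, both flags (`de`, `de_adj`) are reported and the caller
chooses.

Subfamily aggregation sums locus counts per subfamily (`mode="all"`,
exactly conserving totals) or first removes loci overlapping any
protein-coding gene body extended by 10 kb per side
(`mode="intergenic"`), isolating signal from TEs outside genes and
their flanks. Per-subfamily over-representation of upregulated loci is
a one-sided hypergeometric tail on the 2×2 table (up vs not ×
in-subfamily vs not) over the universe of expressed, filter-surviving
TE loci, BH-corrected across subfamilies.

## Cis-regulatory activity (`cis_activity`)

The core model: per-gene deviations in logged expression between
treatment and control are a linear combination of nearby TE
occurrences,

    dE_g = b0 + Σ_s N_gs · a_s + e_g ,

where `N_gs` counts integrants of subfamily *s* overlapping the window
`[TSS_g − 50 kb, TSS_g + 50 kb + 1)` by ≥ 1 bp. Exon-overlapping
integrants never contribute, and subfamilies with fewer than 150 total
gene–integrant colocalizations are dropped (too few occurrences to
identify a coefficient; the "distinct genes" counting variant is
available by flag, pairs is the default). Occurrences are integer
counts, not presence/absence (a binary mode exists). The coefficient
`a_s` — log2 expression units per nearby integrant — is the
subfamily's *cis*-regulatory activity.

The fit is one joint ordinary-least-squares regression over all
retained subfamilies with an intercept (the intercept absorbs
condition-wide shifts so activities reflect TE-linked deviations
only). Inference is the per-coefficient two-sided t-test with
`df = genes − retained_columns − 1`, BH-corrected across subfamily
coefficients within one contrast. Exactly collinear columns are
dropped deterministically — columns are admitted in descending
occurrence-total order (name as tie-break) while they increase the
design rank — and flagged rather than silently regularized;
near-collinearity is left to the t-test's inflated standard errors. A
zero-residual fit returns coefficients with inference fields
undefined (NaN). Activity reports are sorted by adjusted p then
|activity| and binned right-closed at edges (0, 0.01, 0.05, 0.1), so
an activity of exactly 0.05 falls in the 0.01–0.05 bin.

## Single-cell stage (`sc_subfamily`)

Cell QC removes cells with fewer than 200 detected features **or**
more than 25% mitochondrial reads (strict inequalities: a cell at
exactly 200 features and 25% mito is retained; an AND mode and
configurable thresholds are provided since some datasets relax the
mito cut to 20%). Genes must be detected in ≥ 1% of cells, TE loci in
≥ 3 cells; a locus is "expressed" iff it survives this filter
(detection = count ≥ 1 in a cell).

Non-exonic TE loci are summed per subfamily per cell, then values are
depth-normalized to counts per 10,000 per cell and log2(x+1)
transformed. Variance-stabilizing normalization (SCTransform-style) is
not reimplemented: the marker statistic is a rank-sum test, invariant
to any monotone per-cell transformation, so marker calls are
unaffected by this substitution.

Markers are tested per (subfamily, cell type) one-vs-rest with a
two-sided Wilcoxon rank-sum test (one-sided by flag), BH-corrected
across all pairs. The exact null distribution is used whenever both
groups have ≤ 25 observations and no ties occur (the exact regime
covers every case where enumeration is the reference, including
10-vs-10); otherwise the tie-corrected normal approximation applies,
and fully degenerate (all-tied) data returns p = 1.

## Peak enrichment (`peak_enrichment`)

Overlap is counted at the **peak** level: a peak counts once per
subfamily it touches, however many integrants it spans. Two nulls:

* **Shuffle null** — each of K = 10 shuffles replaces every integrant
  uniformly at random on its own chromosome, keeping its length and
  rejecting overlaps with already-placed integrants (bounded at 1000
  retries before a named packing error); this mirrors a
  chromosome-preserving, non-overlapping shuffle background. Fold is
  observed over the mean shuffled overlap; the empirical p uses the
  +1-corrected estimator `(1 + #{shuffles ≥ observed}) / (K + 1)`,
  floor 1/11 at K = 10 (fold, not p, is the graded quantity at this
  K). Zero expected with nonzero observed is flagged infinite. Both
  the raw observed count and the per-integrant-normalized count are
  emitted.
* **Coverage null** — a uniformly placed peak of mean length L̄ hits an
  integrant of length ℓ with probability (ℓ + L̄ − 1)/G; summing over
  a subfamily (capped at 1) gives the per-peak hit probability, a
  binomial expectation and an upper-tail p. A subfamily is significant
  at fold > 2 and p < 0.05. This analytic null is a stated, testable
  stand-in for motif-tool-style background models whose internals are
  not published; it is validated against Monte-Carlo peak placement.

Density tracks convolve base-level TE coverage with a centered
rectangular window of 10 kb and emit bedGraph values every 100 bp;
total mass equals total TE bp up to edge effects.

## Synthetic data (`synthetic_data`)

The generator inverts the analysis assumptions at desk scale. Default
study conditions: 4 chromosomes × 10 Mb; 2000 protein-coding genes
with 1–4 exons; 30 subfamilies × 150 non-overlapping integrants
(300–1500 bp) spanning ERV/LINE/SINE/SVA classes and four age
categories; six subfamilies carry planted activities between −0.05 and
0.15 log2 per integrant; gene-level Gaussian noise σ = 0.3;
negative-binomial replicate sampling (dispersion 0.1, Poisson at 0)
with 3 replicates per condition; 25% of TE loci expressed, three
subfamilies planted 1.5–2 log2-fold up. Single-cell block: five cell
types (60–150 cells), five planted (subfamily, cell type) pairs at
4-fold, Beta-distributed mitochondrial fractions, and a 5% planted
QC-violation fraction (half low-feature, half high-mito cells). Peaks:
500 × 500 bp non-overlapping, with a planted fraction of peaks
centered inside enriched subfamilies' integrants. All randomness flows
from one seed through named substreams; identical configs give
byte-identical output files, and every planted quantity is recorded in
truth JSONs before noise is applied.

What the generator does **not** emulate: read-level artifacts
(mappability, multi-mapping — locus counts are single-assignment, and
the unique-vs-all-reads distinction of real pipelines is represented
by accepting separate input tables), GC or accessibility biases,
doublets/ambient RNA, realistic chromosome-scale TE clustering, or
linkage between the bulk, single-cell and peak blocks beyond the
shared annotation. Passing recovery tests therefore demonstrates
correctness of the estimators under their own model assumptions, not
robustness to real-data violations of them.

## Experiment sizes and numerical choices

The calibration/recovery experiments (`tecre.experiments`, backing
both the acceptance tests and `scripts/acceptance.py`) use: 50
response draws over one 2000-gene genome for activity recovery
(OLS vs an independent SVD solve, ≤ 1e-8 relative; planted activities
within 3 SE; 95% CI coverage), 200 draws for null FDR (BH 0.05 call
rate ≤ 7%), 1000 × 2000 instances for brute-force counting oracles,
and 20 seeds of a 2 × 10 Mb genome with 8000 peaks for enrichment
calibration (null folds within [0.8, 1.25]) and power (expected fold
solved to exactly 3 from the coverage identity; detection = fold > 2
with empirical p at its 1/11 floor). The peak experiments are sized so
each subfamily expects ~100 overlaps under the null, concentrating
null folds well inside the calibration band.

Ties in activity ranking break by |activity| descending; bin edges are
right-closed; the log prior count is 0.5 (configurable); collinearity
detection uses exact rank tests only. Shuffle and placement rejection
sampling is bounded (1000 retries) so infeasible packings fail loudly
with the chromosome named.

## Known limitations

* Welch-t replaces moderated/precision-weighted tests; with very few
  replicates its p-values are noisier than limma-voom's.
* The coverage null ignores chromosome-end effects and
  peak-length variance beyond the mean (exact for fixed-length peaks).
* The activity model is linear and unregularized by design; strongly
  correlated subfamily occurrence patterns yield inflated standard
  errors rather than shrunk estimates.
* Multiple annotated TSSs per gene are reduced to the 5'-most
  (simulation plants a single TSS per gene).
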