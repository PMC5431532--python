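# Methods

`fibrosysmap` re-implements, as a reusable and fully testable pipeline, an
integrated-genomics analysis strategy for idiopathic pulmonary fibrosis
(IPF): consensus differential-expression signatures across heterogeneous
studies, signature-based sample classification, precursor-proxy miRNA
expression, TF–miRNA–gene regulatory-network motif discovery against
degree-preserving nulls, and a pathway-crosstalk permutation statistic.
Every stage runs end-to-end on a synthetic cohort generator, so the whole
analysis is exercised without any external download.

## Differential expression and consensus signatures

Each study is a genes × samples matrix with condition labels. Platform
determines the calling rule:

* **RNA-seq** (integer counts, gene lengths, library sizes): counts are
  converted to RPKM, `count / (length_kb · mapped_millions)`, and a gene is
  called differential when `|log2((m_case + c)/(m_ctrl + c))| ≥ 1` on
  group-mean RPKM with pseudocount `c` (default 1.0, avoiding division by
  zero; the threshold boundary is inclusive).
* **Microarray** (log-intensities): a Welch two-sample t-test per gene,
  called at `p < 0.05`. Genes with zero variance in both groups cannot be
  tested and are excluded with a warning.

These rules deliberately stand in for heavier pipeline-specific machinery
(isoform-aware RNA-seq differential testing, moderated linear models for
arrays): the cutoffs are the scientifically meaningful part for consensus
building, and the simple rules keep the stage self-contained and exactly
testable.

Two consensus constructions are provided:

* **strict intersection** — a gene must be called in *every* input study,
  with one direction throughout (direction checking can be disabled);
* **pairwise consensus** — a gene must be direction-consistently called in
  at least `min_studies` (default 2) distinct studies. Genes called in
  opposite directions by different studies are dropped by default
  (`conflict_policy="drop"`); a `"majority"` policy keeps the direction
  that alone reaches the support threshold. Whether a shared-by-two
  consensus should tolerate direction conflicts is genuinely open; both
  behaviors are exposed and the strict one is the default because a
  direction-inconsistent "signature gene" has no usable interpretation
  downstream (up/up pair filtering, coherence signs).

Gene identifiers are matched as exact case-sensitive strings; no alias
resolution or probe collapsing is attempted.

## Precursor-proxy miRNA expression

When no small-RNA sequencing exists for a cohort, reads from a long-RNA
library that overlap miRNA precursor hairpins still carry expression
information for the precursor, and precursor abundance tracks mature miRNA
abundance well enough to rank differential candidates. The proxy stage:

1. counts reads overlapping each precursor interval — half-open
   coordinates, ≥1 bp overlap, a read counting toward *every* precursor it
   overlaps (no fractional assignment; the simplest rule consistent with
   interval semantics). Counting is unstranded by default (a `stranded`
   flag restricts to matching strands when both are defined);
2. computes per-condition RPKM with library size = **all** reads in the
   library, not only precursor-overlapping ones (precursor reads are a tiny
   fraction of a long-RNA library, and the total is the quantity that
   normalizes sequencing depth);
3. calls up/down at `|log2FC| ≥ 1`.

Multi-study consensus requires the same status in ≥2 studies; when a
sequencing-based proxy status contradicts a microarray status for the same
miRNA, the sequencing status wins *before* support counting (sequencing
measures abundance more directly than hybridization intensity).
Precursor-to-mature mapping is 1:1 by name; an explicit mapping table can
be supplied.

Candidate miRNA–target pairs (an input; no seed-match prediction is done)
are filtered by expression anti-correlation: Pearson `r ≤ −0.7`, boundary
inclusive, on matched profiles of ≥3 samples. Pearson is used for "r"
(the conventional reading of an unqualified correlation coefficient);
zero-variance profiles are dropped with a warning. TF→target edges are
expected to carry *positive* correlation, consistent with activation.

## Classification

Features are Z-scored per dataset (mean 0, sd 1 with the n−1 denominator,
per feature row) so samples from different platforms share a scale.

* **k-means evaluation**: samples are clustered (k = 2, 100 restarts,
  fixed seed) and clusters mapped to the binary labels by the assignment
  minimizing misclassification — so the success rate is never below 50%.
  The reported success rate is rounded to the nearest integer percent and
  displayed with two decimals (4/6 correct → 67.00%). No AUC is reported
  for clustering: hard assignments give no ranking score.
* **cross-validated classification**: stratified 5-fold cross-validation
  repeated 10 times with distinct partitions; the model is a linear
  maximum-margin classifier (linear-kernel SVM, C = 1, configurable — the
  kernel and hyperparameters are not dictated by anything in the data, so
  the simplest standard choice is the default). Out-of-fold predictions
  are pooled per repeat; accuracy, sensitivity, specificity, AUC (from the
  decision function) and MCC are reported per repeat and as means.

MCC is computed as `(tp·tn − fp·fn)/√((tp+fp)(tp+fn)(tn+fp)(tn+fn))` with
the value 0 by convention when a denominator factor vanishes (constant
prediction).

## Regulatory network and feed-forward loops

The regulatory graph is directed with three disjoint node classes and four
edge types: TF→gene, TF→miRNA, miRNA→gene, miRNA→TF. Assembly
deduplicates edges and rejects any edge whose declared type contradicts its
endpoint classes. Metrics: in/out degree, unnormalized betweenness,
closeness on each node's reachable set. Hubs: top five TFs and miRNAs by
out-degree, top five genes by in-degree, ties broken lexicographically.

Feed-forward loops:

* 3-node **TF-FFL**: TF→miRNA, TF→gene, miRNA→gene;
* 3-node **miRNA-FFL**: miRNA→TF, TF→gene, miRNA→gene;
* 4-node **composite**: one TF and one miRNA that both regulate the same
  two genes, plus an edge (either direction) between the regulators. The
  two-regulator/two-target shape is the default 4-node topology;
  alternative shapes would be easy to add but are not enabled.

Each motif is emitted once with canonical node ordering; a TF/miRNA pair
linked in both directions yields both 3-node classes on the same triangle
(they are different circuits). Enumeration is verified against an
exhaustive scan over all class-valid node triples/quadruples on randomly
generated networks.

Modules are k-clique-percolation communities (k = 3) of the undirected
simple projection of the graph — the mixed-direction regulatory graph has
no canonical directed-clique notion, and percolation communities are
defined on undirected cliques. Verified against brute-force clique-graph
components.

### Motif null model

Randomized networks are produced by double-edge swaps **confined within
each edge type** (Q = 10 attempted swaps per edge), which preserves every
node's per-type in/out degree sequence exactly — and therefore also its
joint degree. Swapping across types would manufacture class-forbidden
edges (e.g. gene→TF), so within-type swapping is the only sound choice.
Swaps creating duplicate edges are rejected; self-loops cannot arise
because every edge type joins two different classes.

Each observed motif is scored individually: `p = (1 + B)/(1 + N)` where
`B` counts randomized networks (N = 1000) containing the same typed
circuit on the same node set, and motifs with `p ≤ 0.05` are retained.
The `+1/+1` smoothing keeps p away from an unattainable 0. A per-motif
criterion (rather than an aggregate motif-count z-score) is used because
the pipeline filters *individual* circuits for downstream interpretation.

**Statistical caveat — this statistic is not a calibrated p-value.** The
quantity being estimated is the probability that a specific circuit exists
in the degree-preserving ensemble. In a sparse network that probability is
roughly the product of three small per-edge probabilities, so essentially
*every* observed motif scores "significant"; in a dense network the same
product may exceed α for every motif and nothing is retained. The retained
fraction under a null (random) network is therefore a step-like function
of density, not the nominal 5% — the acceptance script measures it
honestly (`ffl_null_retained_pct`, ≈80–100% on a dense random network).
The statistic is still useful as a *specificity screen* (circuits forced
by degree structure alone score high p, as the tests demonstrate with
motifs whose edges are unswappable), but its threshold should not be read
as a false-positive rate.

## Pathway crosstalk

Pathways (GMT gene sets) are first filtered to ≥6 members, optionally
after intersection with a context gene set. For a pathway pair, the
statistic is the number of PPI edges (confidence ≥ a cutoff, default 0 for
counting) joining A-only to B-only members — genes in A∩B are excluded
from both sides, since edges inside the overlap are not "between" the
pathways (a flag restores them).

The null shuffles each pathway 1000 times by replacing every gene with a
random gene of the same PPI degree, sampled without replacement within the
pathway; pathway genes absent from the PPI form the degree-0 class. Exact
degree classes with fewer than 5 candidates are expanded with the nearest
classes by |log1p(d) − log1p(d′)| — exact matching is routinely infeasible
in the tail of a power-law degree distribution. All pathways are shuffled
once per replicate and all pairs recounted, so null counts share
replicates across pairs (cheap, and irrelevant to per-pair validity).
`p = (1 + #{null ≥ observed})/(1 + N)`. On a tiny universe the sampled p
is verified against exhaustive enumeration of all degree-matched
assignments.

**Calibration.** Because each original pathway is exchangeable with its
degree-matched shuffles under the synthetic null, the empirical p is
exactly valid: the false-positive fraction never exceeds the nominal rate.
It is, however, *conservative* when counts are heavily discrete: at the
generator's default PPI density the null inter-pathway count has mean ≈1,
only counts ≥4 can reach p ≤ 0.05, and the measured null false-positive
rate is ≈2% rather than 5% (`crosstalk_null_fpr_pct` in the acceptance
output). Raw empirical p at 0.05 is the default multiple-testing stance
(one pair = one planned test), with an optional BH switch.

Significant pairs are flagged `passes_up_up` when both pathways contain at
least one upregulated consensus gene. High-confidence first neighbors
(confidence ≥ 500, boundary inclusive — the conventional reading of a
STRING-style "confidence of 500" cutoff) extend the gene context, and
enrichment uses the one-sided hypergeometric tail with Benjamini-Hochberg
adjustment at q < 0.05. "Benefited" and "compromised" system chains are
operationalized as enrichment run separately on the up- and down-regulated
partitions of the neighborhood; this is an interpretation — the concept
names a phenomenon, not an algorithm — and is documented as such.
Unweighted edge counting is used throughout (confidence enters only as a
threshold).

## Synthetic cohort generator

One master seed expands into independent per-stage child seeds
(`numpy.random.SeedSequence`; stage order: expression, regulatory, PPI,
reads, miRNA-microarray), so any stage regenerates bit-for-bit on its own.

What it emulates, and the reference conditions (the defaults):

* **Expression** — 5 studies (2 RNA-seq, 3 microarray), 2000 genes, each
  study covering a uniform random 80% of the universe (emulating unequal
  probe coverage), 10 samples per group. Microarray: Gaussian
  log-intensities, per-gene baseline N(8, 1.5²), noise sd 0.5 — a typical
  mid-range array noise level. RNA-seq: negative-binomial counts
  (dispersion 0.1, ~tissue-level biological variability), log-normal
  baseline means, gene lengths uniform 0.5–5 kb, library size = column
  sum. 40 planted DEGs (half up, half down) shifted by exactly
  `effect_size` (default 4) log2 units in cases. The effect size is large
  by design: planted-recovery tests probe the *machinery*, not borderline
  power. Optional NSIP/Sarcoidosis groups carry a half-magnitude,
  partially sign-flipped signature.
* **Regulatory tables** — 30 TFs and 40 miRNAs with 8 targets each
  (mostly genes, occasionally the other regulator class); a configurable
  coherent subset (default 50% of gene-targeting edges) has target
  profiles resampled so TF-target r > 0 and miRNA-target r ≤ −0.7, one
  constraint per target; 5 planted TF-FFL triples.
* **PPI and pathways** — Chung-Lu expected-degree graph with power-law
  exponent 2.5 and mean degree 8 over the gene universe, confidences
  uniform in [150, 1000]; 12 random pathways of 8–25 genes; 2 planted
  crosstalk pairs with 30 excess high-confidence inter-pathway edges.
* **Precursor reads** — ~100 bp precursor intervals, 36 bp reads, Poisson
  read counts (mean 60 per precursor), 10 planted differential precursors
  at 4-fold, plus 20 000 background reads off-target that contribute to
  library size only.

What it does **not** emulate: probe cross-hybridization, GC/length bias,
sequencing error, batch effects, correlated gene-gene noise, realistic
pathway overlap structure, or any specific public dataset. Passing the
planted-recovery tests therefore demonstrates that the pipeline's logic
and thresholds behave as designed under known ground truth — not that the
thresholds are optimal for any particular real cohort.

## Numerical choices and degenerate inputs

* Boundary semantics are inclusive wherever a threshold is stated as
  "≥"/"≤" (log2FC ≥ 1, r ≤ −0.7, confidence ≥ 500, ≥6 pathway genes).
* Empirical p-values always use the `+1/+1` smoothing; their range is
  `[1/(N+1), 1]` and is asserted in tests.
* Zero-variance features: dropped with a warning (Z-scoring, microarray
  testing, correlation filtering) rather than propagating NaNs.
* Hub and cluster ties break deterministically (lexicographic node id;
  lower cluster index).
* Networks with no swappable edge pair randomize to a copy, logged.
* Degree classes exhausted during pathway shuffling fall back to the
  remaining universe, logged (cannot occur with default pool expansion).

## Problem sizes

The test-suite and the acceptance script run the reference cohort at its
default sizes (2000 genes, 5 studies, ~575 regulatory edges, 1000
randomizations / shuffles) and complete in well under a minute each on a
single CPU; oracle-equivalence suites use networks of ≤60 nodes where
exhaustive scans are exact and fast. These sizes were chosen so that every
Monte-Carlo assertion has adequate precision (e.g. 435 pathway pairs for
the ±2-point calibration checks) while brute-force oracles remain feasible.

## Known limitations

* The per-motif presence statistic is not a calibrated p-value (see the
  motif null-model caveat above).
* The crosstalk permutation test is conservative under heavily discrete
  counts; with sparse PPIs its effective size is below nominal.
* Success-rate percentages follow the integer-percent rounding convention;
  published tables in this field sometimes use other conventions, which
  cannot be inferred from (total, misclassified) pairs alone.
* No identifier mapping: all inputs must share one gene/miRNA namespace.
* The linear-SVM default is a reasonable, not tuned, classifier; the
  cross-validation harness accepts any scikit-learn-compatible
  regularization setting via `C`.
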