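# fibrosysmap

An integrated-genomics analysis toolkit for idiopathic pulmonary fibrosis
(IPF) — and, more generally, for any disease condition studied through a
heterogeneous collection of case/control expression studies. IPF
transcriptomics is notoriously inconsistent across cohorts and platforms;
`fibrosysmap` provides the machinery to distill that heterogeneity into
robust signatures and system-level structure:

* **Consensus differential-expression signatures** across microarray and
  RNA-seq studies: per-study calls (Welch t-test at p < 0.05 for arrays,
  |log2FC| ≥ 1 on RPKM for RNA-seq), then strict-intersection or
  shared-by-≥k-studies consensus sets with direction checking.
* **Signature-based sample classification**: Z-scored features, k-means
  cluster-to-label evaluation, and repeated stratified 5-fold
  cross-validation of a linear SVM with accuracy / sensitivity /
  specificity / AUC / MCC.
* **Precursor-proxy miRNA expression**: when no small-RNA sequencing
  exists, reads of a long-RNA library overlapping miRNA precursor
  intervals proxy mature miRNA abundance; differential precursors are
  combined across studies with sequencing-over-array conflict resolution,
  and candidate targets are filtered by anti-correlation (Pearson
  r ≤ −0.7).
* **TF–miRNA–gene regulatory networks and feed-forward loops (FFLs)**:
  typed directed graphs, hub and centrality analysis, exhaustive 3-/4-node
  FFL enumeration, k-clique-percolation modules, and per-motif empirical
  significance `p = (1 + B)/(1 + N)` against N = 1000 networks randomized
  by degree-preserving, edge-type-confined double-edge swaps.
* **Pathway crosstalk**: for every pathway pair, the count of PPI edges
  joining exclusive members is tested against 1000 degree-matched gene
  shuffles; significant pairs are filtered for upregulated genes on both
  sides, extended by confidence-≥500 first neighbors, and profiled by
  hypergeometric/Benjamini-Hochberg enrichment.

A synthetic-cohort generator (`fibrosysmap.synthetic`) produces every
input format with known planted structure — DEGs, coherent regulatory
edges, FFLs, differential precursors, crosstalking pathway pairs — so the
entire pipeline is testable end-to-end, offline, from one seed.

## Worked example

One command runs the full synthetic analysis:

```bash
fibrosysmap demo --seed 1 --outdir demo_run
```

which prints (excerpt):

```json
{
  "set_a_size": 26,
  "set_b_size": 43,
  "planted_deg_recovery_pct": 100.0,
  "planted_demir_recovery_pct": 100.0,
  "kmeans_success_rate_pct": 100.0,
  "cv_mean_accuracy": 1.0,
  "cv_mean_mcc": 1.0,
  "ffl_counts": {"TF-FFL": 7, "miRNA-FFL": 0, "composite-4": 0},
  "ffl_significant": 7,
  "cpm_modules": 7,
  "crosstalk_significant": 4,
  "planted_crosstalk_p": {
    "PW001~PW002": 0.000999000999000999,
    "PW003~PW004": 0.000999000999000999
  }
}
```

Reading the numbers: the five synthetic studies carry 40 planted
differential genes; the shared-by-≥2-studies consensus ("set B", 43 genes)
recovers all of them plus a handful of threshold-crossing noise genes,
while the strict two-study intersection ("set A") holds 26. The planted
classification signal separates cases perfectly (success rate 100%,
cross-validated accuracy and MCC 1.0). The regulatory network (30 TFs,
40 miRNAs, 431 targeted genes, 575 typed edges) contains the 5 planted
feed-forward loops among its 7 enumerated ones, all retained at the 5%
level against 1000 degree-preserving randomizations. Both planted
crosstalk pathway pairs score the minimum attainable empirical p,
1/1001 ≈ 0.001. Every intermediate table (DEG calls, consensus sets,
motif and crosstalk reports, run manifest) is written under `demo_run/`.

The same machinery is exposed for real data through the library API and
the `classify`, `motifscan` and `xtalk` subcommands, which consume plain
TSV/GMT/BED inputs:

```bash
fibrosysmap xtalk --pathways pathways.gmt --ppi ppi.tsv \
    --min-genes 6 --n-random 1000 --seed 7 --out crosstalk.tsv
```

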