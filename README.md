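# fibrosort

Cross-modal discovery and validation of stromal cell subsets from sorted
bulk and single-cell transcriptomes — implemented end to end on synthetic
cohorts with known ground truth.

## The problem

In rheumatoid arthritis (RA), synovial fibroblasts drive chronic
inflammation and joint destruction, but "fibroblast" hides real
heterogeneity. Flow cytometry of PDPN⁺ synovial stromal cells resolves
seven gated populations by CD34, THY1 and CDH11 surface markers; the
analytical question is whether those gates correspond to genuinely
distinct transcriptional subsets, and whether subset proportions differ
between RA and osteoarthritis (OA). `fibrosort` implements that analysis
as a reusable, tested pipeline:

1. **Discovery (bulk).** Donor effects are removed from gated bulk
   profiles by per-gene OLS residualization; a one-way ANOVA across the
   7 gates with Benjamini–Hochberg control (1% FDR) flags subset-variable
   genes; specificity-scaled PCA and hierarchical clustering of pairwise
   Pearson correlations collapse the 7 gates into 3 major subsets
   (CD34⁻THY1⁻, CD34⁻THY1⁺, CD34⁺).
2. **Validation (single cells).** Cells with ≥ 5,000 detected genes are
   clustered on genes in the top 1% of both mean and variance; agreement
   with gate labels recorded at sort time is scored by the adjusted Rand
   index and tested by label permutation (add-one p-value, floor
   1/(B+1)).
3. **Transfer (LDA).** A shrinkage-regularized linear discriminant model
   is trained on bulk subsets over two-stage-selected genes (pairwise DE
   at 5% FDR, single-cell mean log2(TPM) > log2(10)) and assigns each
   cell a posterior over the three subsets.
4. **Cohort statistics.** Per-donor subset proportions are compared
   between RA and OA by Wilcoxon's rank-sum test at a Bonferroni
   threshold of 0.05/3, with a logistic-regression odds ratio per
   10-percentage-point increase, and correlated with inflammation
   covariates (Spearman / OLS).

A first-class synthetic-data module generates bulk, single-cell and
proportion cohorts with planted subsets, donor offsets, logistic dropout
and tunable gate fidelity, so every stage is testable without any data
download. See `docs/methods.md` for the model and all numerical choices.

## Worked example

Run the full study-scale pipeline (19,500 genes; 7 gates × 7 donors bulk;
384 cells from 4 donors; 16 RA / 26 OA proportion cohort) from one seed:

```bash
fibrosort run --seed 1 --outdir out/
```

which prints the headline metrics of the run:

```json
{
  "anova_significant_genes": 605,
  "sc_selected_genes": 9,
  "cluster_gate_ari": 0.7474950691500676,
  "cluster_truth_ari": 0.9549189092740475,
  "permutation_p": 0.0001,
  "lda_gene_count": 559,
  "median_max_posterior": 1.0,
  "proportion_rmse": 0.02157951891433343,
  "classification_accuracy_vs_truth": 1.0,
  ...
}
```

Reading these numbers: 605 genes vary across the 7 gates at 1% FDR
(600 were planted); single-cell clusters agree with the sort-time gate
labels at ARI 0.75 — limited by the planted 10% gate-mislabel rate, not
by the clustering, which reaches ARI 0.95 against the true subsets — and
permuting gate labels 9,999 times never reaches the observed agreement
(p = 1e-4, the add-one floor). The bulk-trained LDA classifies all cells
correctly (median maximal posterior 1.0), and classifier-derived subset
proportions match gate-derived ones to RMSE 0.022. The cohort stage
(in `out/cohort/group_comparisons.tsv`) recovers the planted expansion of
the CD34⁻THY1⁺ subset in RA (medians ≈ 20% vs 7%, Wilcoxon p ≪ 0.017).

Each stage is also a library function (`fibrosort.anova_across_gates`,
`fibrosort.permutation_concordance`, `fibrosort.fit_lda`, ...) and a CLI
subcommand (`simulate`, `preprocess`, `discover`, `sc-cluster`,
`classify`, `cohort`) operating on TSV/MTX files.

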