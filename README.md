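# neomix

Multi-omics stratification of lung neuroendocrine neoplasms (LNENs):
pulmonary carcinoids (typical and atypical), large-cell neuroendocrine
carcinoma (LCNEC) and small-cell lung cancer form a spectrum whose
histopathological boundaries — especially atypical carcinoid vs LCNEC — are
hard to draw and prognostically consequential.  `neomix` implements, as a
tested and reusable pipeline, the integrative analysis used to stratify
such cohorts from bulk RNA-seq counts and array methylation β-values:

- **Joint latent-factor decomposition** of the expression and methylation
  blocks (deterministic EM-SVD matrix completion, so samples missing one
  whole omic block still receive scores), with per-block variance-explained
  accounting, a ≥2% retention rule, stability checks, and factor–covariate
  / factor–mutation / loading–gene-set association tests.
- **Consensus clustering**: k-means on the leading `K−1` factors (or
  variance-weighted k-means on all factors) over 100 subsample-refit
  replicates; pairwise consensus values, a median-linkage consensus
  hierarchy, and Dunn-index selection of the number of clusters.
- **Dual-omic classification**: one random forest per omic under
  leave-one-out cross-validation with per-fold normalisation and
  variable-feature selection (50% of expression variance, 5% of methylation
  variance), minority oversampling, an **Unclassified** category for samples
  whose top-two class-probability ratio falls below 1.5, and rules for
  merging expression- and methylation-based predictions.
- **Differential analysis**: empirical-Bayes moderated linear-model tests
  with a fold-change-threshold null (|log2 FC| > 2 for expression), core
  features as intersections of all pairwise comparisons, promoter CpG
  mapping (±2000 bp around the TSS) and methylation–expression Pearson
  filtering (q < 0.05, r² > 0.5, IQR(β) > 0.25).
- **Immune deconvolution**: constrained least squares (`f ≥ 0`, `Σf ≤ 1`,
  explicit non-immune remainder) over a ten-cell-type signature, with
  exact/Monte-Carlo permutation tests for group differences.
- **Survival**: Kaplan–Meier curves, Newton–Raphson Cox proportional
  hazards with Efron tie correction (Wald and logrank tests), elastic-net
  Cox gene selection (α = 0.5, leave-one-out deviance, one-standard-error
  rule), and maximally selected rank-statistic expression cutpoints
  (minimum 10% of samples per side).
- **Mutation enrichment**: Fisher-exact tests of mutation events (counted
  with multiplicity) in hallmark gene sets, BH-adjusted, with by-sample and
  by-gene jackknife leverage diagnostics.

Because the underlying patient data are controlled-access, the package
ships a seeded **synthetic-cohort generator** that plants the structure
these analyses assume — three molecular clusters, a small "supra" group
whose morphology label contradicts its molecular profile, optional
intermediate mixtures, cluster-dependent survival, cluster-enriched
mutations, methylation-driven genes, an immune mixing signal, and samples
missing one omic block — so every stage is exercised end to end with no
data download.

## Worked example

```python
from neomix import SimConfig, generate_cohort
from neomix.preprocess import (drop_sex_chromosome_features, filter_low_expression,
                               normalize_expression, beta_to_m, select_variable_features)
from neomix.factors import fit_joint_factors, select_factors, standardize_block
from neomix.clustering import consensus_cluster

cohort = generate_cohort(SimConfig(seed=0))          # 120 samples, 3 planted clusters
expr = filter_low_expression(drop_sex_chromosome_features(cohort.expression, cohort.annotation))
en = normalize_expression(expr)
mv = beta_to_m(drop_sex_chromosome_features(cohort.methylation, cohort.annotation))
blocks = {
    "expression": standardize_block(en.loc[select_variable_features(en, 0.5)])[0],
    "methylation": standardize_block(mv.loc[select_variable_features(mv, 0.05)])[0],
}
model = select_factors(fit_joint_factors(blocks, K=5), min_varexp=0.02)
print(model.varexp.round(3))
res = consensus_cluster(blocks, K_range=range(2, 6), R=100, seed=0)
print("chosen K:", res.chosen_k, " Dunn:", {k: round(v, 3) for k, v in res.dunn_per_k.items()})
```

prints (cohort seed 0):

```
               LF1    LF2    LF3
expression   0.446  0.436  0.029
methylation  0.910  0.001  0.013
chosen K: 3  Dunn: {2: 0.059, 3: 0.163, 4: 0.049, 5: 0.049}
```

Three factors clear the 2% retention rule, and the two leading ones carry
the cluster structure — LF1 dominating the methylation block, LF2 the
expression block.  The Dunn index peaks at K = 3, recovering the three
planted molecular clusters (adjusted Rand index 0.94 against the planted
labels).

The full pipeline (simulate → preprocess → factorize → cluster → classify →
differential → deconvolution → survival → enrichment) runs from a single
config:

```bash
neomix run --seed 7 --out results_dir            # or: neomix run --config my.yaml
neomix simulate --seed 3 --out cohort_dir        # just the synthetic cohort
```

Each run writes TSV artifacts, a `manifest.yaml` recording every parameter
and derived stage seed, and a plain-text `report.txt` (chosen K, Dunn table,
confusion matrix, prognostic groups, core-gene counts, enrichment flags).
Identical config + seed reproduces byte-identical artifacts.

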