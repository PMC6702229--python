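# Methods

This note documents the models and procedures implemented in `neomix`,
their assumptions, the defaults that matter, and what the synthetic cohort
does and does not emulate.

## Joint latent-factor model

The two omic blocks — log2-normalised expression and methylation M-values,
each restricted to its most variable features, centred per feature and
rescaled to unit total block variance — are stacked and approximated by a
shared rank-K factorisation `X ≈ W Zᵀ` (unit-norm loadings `W`, sample
scores `Z`).  The fit is deterministic EM-SVD matrix completion: missing
entries (whole omic blocks for some samples) are imputed from the current
rank-K reconstruction (zeros initially), a truncated SVD of the completed
matrix is taken, and the steps alternate.  This is a deliberate surrogate
for variational-Bayes group factor analysis: downstream stages consume only
the factor subspace, scores, loadings and variance-explained fractions, and
PCA-style features are known to produce qualitatively equivalent
stratifications on this class of data; determinism buys exact
reproducibility and testability.

Numerical choices:

- **Convergence** is declared when the relative decrease of the
  observed-entry reconstruction error falls below `tol` (default 1e-6,
  max 100 iterations).  The reconstruction itself is not a usable
  criterion: trailing factors with near-equal singular values rotate
  freely in the noise subspace without changing the objective.
- **Missing-sample scores.** At the EM fixed point the score of a sample
  missing a block equals the least-squares projection of its observed
  block onto the loadings.  That projection is computed directly after the
  loop; without it, scores of block-missing samples remain shrunk towards
  the zero initialisation and form a spurious central subgroup that
  corrupts clustering.  For fully observed samples the projection equals
  the SVD score exactly (residuals are orthogonal to the loading columns).
- **Identifiability.** Each factor's largest-magnitude loading is made
  positive and factors are ordered by total variance explained, so two
  runs are comparable entry-wise.
- Variance explained per block and factor is
  `‖w_mk‖² · Σ_{j∈obs(m)} z_jk² / ‖X_m‖²` over observed entries; factors
  with <2% variance explained in both blocks are dropped (configurable).
- Because the fit is deterministic there is no evidence-bound-based run
  selection; `factor_stability` instead refits with noise-perturbed
  initial imputations and reports cross-run factor correlations.

## Consensus clustering

Each of R = 100 replicates draws an 80% subsample without replacement,
refits the factor model on it, and partitions the replicate's standardized
factor scores with k-means (k-means++, 25 restarts).  The consensus value
of a sample pair is its co-clustering rate among co-sampled replicates;
pairs never co-sampled raise an error rather than being silently imputed.
Final labels come from a median-linkage hierarchy of (1 − consensus) cut at
K.

Two modes: `kminus1` clusters on the leading K−1 factors; `weighted` uses
all retained factors with per-factor weights equal to their total
variance-explained share inside the squared distance (implemented by
scaling standardized coordinates with √weight).  When the factors beyond
K−1 are pure noise the two modes produce identical partitions, which the
test suite checks across 20 generator seeds.

**Scaling and model selection.**  Factor scores are standardized before
clustering: raw SVD scores carry the singular values, which compresses the
axis separating the two carcinoid-like groups relative to the
carcinoid-vs-high-grade axis and distorts distances.  The number of
clusters is chosen by the Dunn index (minimum between-cluster distance over
maximum cluster diameter).  Because Dunn values for different K are only
comparable in one geometry, every candidate K is scored in a common space —
the standardized leading factors jointly covering ≥90% of the total
variance explained (at least two) — on the full-data k-means partition at
that K.  Scoring the hierarchy labels instead is fragile: one borderline
misassignment collapses the between-cluster minimum, and median-linkage
cuts like to peel outliers into tiny clusters that the Dunn ratio rewards.
The consensus hierarchy still provides the reported partition at the chosen
K.  Dunn remains a minimax statistic; on weakly separated data its K choice
is noisy, which is a property of the index, not of the estimator of it.

## Dual-omic classification

One random forest per omic (500 trees, √p candidate features per split,
seeded), evaluated by leave-one-out cross-validation.  Everything that can
leak is learned inside the fold: the expression CPM filter, the
median-of-ratios reference profile, the variance-fraction feature selection
(50% expression / 5% methylation), and the centre/scale statistics; the
held-out sample is transformed with the training model.  Declared technical
replicates are never split across train and test.  Minority classes are
oversampled with replacement to the majority size after feature selection,
so duplicated samples cannot inflate the variances used for selection.
Class probabilities are per-tree vote fractions — deterministic across
implementations, unlike leaf-probability averaging.

A sample is **Unclassified** when its top-two class-probability ratio is
below ρ = 1.5; a ratio of exactly ρ is classified (the comparison carries a
1e-12 relative tolerance because vote-count ratios like 3:2 are not exact
in floating point), and an exact tie is always Unclassified since the
argmax itself is undefined.  Per-omic predictions merge by: one omic only →
that prediction; agreement → that label; Unclassified + class → the class;
two different classes → Unclassified.  Survival comparisons use
(histology, prediction) groups with all Unclassified samples pooled and
groups of ≤10 samples excluded.

## Differential analysis

Expression and methylation differential tests share one engine: per
feature, a linear model `value ~ group + covariables` on the two groups of
a pair, with empirical-Bayes moderation of the residual variances.  The
prior `(s0², d0)` is estimated by matching the mean and variance of the log
residual variances to the digamma/trigamma moments of the scaled-F model;
`d0 = 0` recovers the classical t, `d0 = ∞` (returned when the observed
log-variance spread is at or below pure chi-square noise) shrinks every
variance to `s0²`.  The statistic embeds a fold-change threshold θ:
`t = max(|b| − θ, 0) / (s̃ c)` on `d0 + d` degrees of freedom — a
TREAT-style test of the null that the true effect is smaller than θ.
Defaults: θ = 2 (log2) for expression, θ = 0 for methylation.  BH
adjustment is applied within each pairwise family.  This unifies what the
original analyses did in two frameworks (negative-binomial Wald tests for
counts, array linear models for M-values); it is a surrogate for the NB
likelihood on the expression side.

Core features of a focal group are the intersection, over all pairs
involving it, of significant features with a consistent effect direction
relative to the focal group (the direction requirement is a documented
interpretation and can be disabled).  Promoter CpGs are those within
±2000 bp of a TSS on the same chromosome (boundary inclusive; a CpG may
serve several genes).  Methylation–expression correlation keeps pairs with
q < 0.05, r² > 0.5 and IQR(β) > 0.25 and reports the smallest-q CpG per
gene with its sign.

## Immune deconvolution

Bulk expression over the signature genes is modelled as `b ≈ S f` with
`f ≥ 0` and `Σf ≤ 1`; the slack `1 − Σf` is the non-immune ("other")
content.  Non-negative least squares solves the generic case; when the
simplex bound is active an SLSQP refinement enforces it.  Group differences
in fractions are tested by permutation on the group-mean difference —
exhaustive enumeration whenever the number of label splits fits the
permutation budget (exact p-values), seeded Monte-Carlo with the add-one
correction otherwise — BH-adjusted across cell types within each pair.
Exact permutation p-values at small group sizes are discrete and
conservative; that is intrinsic, and it is why the original analyses used
permutation tests for their smallest groups.  The bundled signature matrix
is synthetic (six marker genes per cell type, ten cell types); any
user-supplied genes × cell-types TSV on the same scale as the bulk works.

## Survival

Kaplan–Meier estimation and the global logrank test use lifelines.  The
Cox proportional-hazards fit is an in-package Newton–Raphson maximiser of
the Efron-corrected partial likelihood (analytic gradient and Hessian,
step halving, convergence at max-gradient 1e-10), with Wald statistics from
the observed information.  A wrapped general-purpose fitter was abandoned
because its convergence criterion leaves ~1e-5 coefficient error on small
tied datasets, visible against the package's own partial-likelihood oracle
tests; the in-package Newton solver agrees with independent numerical
maximisation to ~1e-8 and with lifelines to its own tolerance on regular
data.  Monotone-likelihood and separation cases are returned flagged, not
raised.  Breslow ties are available via a flag.

Elastic-net Cox gene selection (α = 0.5 by default) uses the
coordinate-descent path of scikit-survival over 100 λ values spanning four
decades below λ_max, with leave-one-out cross-validated partial-likelihood
deviance in the Verweij–Van Houwelingen form
`dev_i = −2 (ℓ_full(β₋ᵢ) − ℓ₋ᵢ(β₋ᵢ))` and the one-standard-error rule
(largest λ within one SE of the minimum mean deviance).  α = 0 (pure
ridge) falls outside the coordinate-descent parameterisation and is served
by an L2-penalised fit; it never produces exact zeros, as expected.
Expression cutpoints are maximally selected standardized logrank
statistics over midpoints between consecutive distinct marker values,
with at least 10% of samples on each side; the reported p-value is the
unadjusted logrank p of the chosen split (the selection-adjusted p is out
of scope).  Survival time is months throughout; "10-year" means 120
months.

## Mutation / hallmark enrichment

For a sample group and gene set, a 2×2 Fisher-exact table contrasts
mutation events inside vs outside the set — events counted with
multiplicity across samples and recurrently mutated genes (a
presence/absence mode is available, since the original contingency
construction is ambiguous) — against the in-set vs out-of-set gene
composition of the declared universe (default: all mutated genes union all
set genes).  BH across sets within the group; flags at both the 5% and 10%
FDR.  Jackknife re-testing after removal of each sample or each mutated
gene reports which significance calls depend on a single unit.

## Synthetic cohort

The generator plants exactly the structure the pipeline assumes, at a desk
scale chosen once: 120 samples (54 + 38 + 24 core clusters, 4 supra, 0
intermediate by default; classifier experiments use 50 + 36 + 22 + 4 + 8),
2000 genes, 2000 CpGs, three latent factors of which two separate the
clusters.  Expression counts are negative-binomial
(`variance = μ + φμ²`, φ = 0.1) with
`log μ = baseline + loadings·scores + log library size`; methylation
M-values are `loadings·scores + N(0, 0.5²)` mapped to β by the inverse
M-transform and clamped to [1e-6, 1−1e-6].  Methylation loadings have flat
magnitude (0.6, random sign) and denser support than expression loadings,
mimicking the diffuse variance of arrays and making the methylation block
informative enough that samples missing expression are still well
localised — as in the real setting, where methylation alone supports
accurate classification.  Fifty genes are methylation-driven (their
promoter CpG's M-value enters the expression log-mean with coefficient
−0.8); sixty genes carry a linear immune-mixing signal from planted
per-sample cell-type fractions; eight X- and four Y-linked genes give the
sex-concordance QC something to detect.  Survival is exponential with
per-cluster log-hazards (−3.6, −2.9, −1.6 per month, so the LCNEC-like
cluster dies fastest), censored with probability 0.3 at a uniform fraction
of the event time.  Supra samples carry the atypical morphology label with
the LCNEC-like molecular profile and hazard; intermediates are 50/50
mixtures of the atypical-like and LCNEC-like profiles — the boundary where
real diagnoses are hardest.  Ten percent of samples lack expression and a
disjoint ten percent lack methylation, realised as absent columns.
Between-cluster effect sizes are deliberately strong: the published cohort
does not state them, and the package's tests are parameter-recovery checks
that require the planted structure to be identifiable at n = 120.

What the generator does **not** emulate: probe-level array artefacts and
batch chemistry (only a nominal batch column is provided), linkage between
neighbouring CpGs, realistic genome coordinates, copy-number or fusion
events, overdispersion that varies with expression level, and intermediate
phenotypes more graded than a two-component mixture.  Passing tests
therefore demonstrate that the estimators recover structure they are
designed for, at realistic sample sizes and missingness — not that the
pipeline is robust to every artefact of real cohorts.

## Problem sizes in the test suite

The suite runs the full default cohort where a criterion demands it
(consensus clustering with R = 100; the dual-omic classifier with 500
trees) and scaled-down versions elsewhere (smaller cohorts for pipeline
smoke tests, 12–15 consensus replicates, 20–40 forest trees), with the
sizes stated in each test.  Simulation-based checks use 20–200 replicates
as specified by the property being tested.
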