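# Methods

This note records the statistical models implemented in `bloodmark`, the
defaults and why they were chosen, what the synthetic cohort does and does
not emulate, and the numerical conventions that matter for reproducing
results.

## Synthetic cohort model

The generator (`bloodmark.simulate`) emulates a 30-subject bulk RNA-seq
study of three groups (control / MA / MAP, n = 10 each) at desk scale:
2000 genes by default (a full-scale cohort is available by raising
`n_genes`; all analyses are O(n_genes²)–O(n_genes³) in the network stage).

* **Counts.** Gene-wise base abundance is log-normal
  (`base_log2 ~ N(5, 2²)` on the log2 scale). Observed counts are
  negative-binomial around library-size-scaled expected expression with
  gene-shared dispersion 0.1 — the standard bulk RNA-seq observation model
  with a moderate biological coefficient of variation (~0.32). Library
  sizes are log-normal with mean 2 × 10⁶ and CV 0.1, so column sums
  concentrate near the configured mean. Relative abundances are normalized
  per subject, which makes library sizes exact in expectation at the cost
  of a (negligible, ~1/n_genes) compositional coupling between genes.
* **Modules.** Eight planted modules of 100 genes each. Every module has
  one latent factor per subject (`N(0,1)`), and member genes load on it
  with loadings `N(1.0, 0.2²)` added to their log2 expression. With the NB
  noise at these abundances this yields within-module log-scale
  correlations around 0.6–0.8, comparable to a strong co-expression module,
  and a clean target for recovery tests. The remaining 1200 genes are
  uncorrelated background.
* **Group effects** shift a module's factor mean per group on the log2
  scale (defaults: module 0 MAP −1.0; module 1 MAP +1.0 / MA +0.4; module
  2 MA +0.8), i.e. roughly one log2 unit of expression change for a gene
  with unit loading — a large but realistic bulk effect.
* **Phenotypes** are linear in the module factors plus Gaussian noise
  (e.g. left hippocampal volume and K10 distress couple to module 0,
  psychoticism to module 1), with baselines at anatomically sensible
  volumes (mm³) and instrument totals. Substance-use counts are noisy
  functions of the *confounder module's* factor (the last module by
  default), which carries no group effect; this makes confounder-module
  exclusion testable end to end.
* **Evidence database.** Genes in enriched modules receive 1–3 literature
  records with probability 0.5 (modules 0–1) or 0.1 (modules 2–3); records
  lean toward blood-expression/psychosis lines so that the CFG blood
  weighting is exercised. Genes outside enriched modules receive records at
  `background_evidence_rate` (default 0).

What the generator does **not** emulate: between-sample normalization
artifacts (GC/length bias, batch), overlapping or nested modules,
non-linear phenotype couplings, medication effects, count outliers, or the
long-tailed module-size distribution of real co-expression networks.
Passing recovery tests therefore demonstrate correctness of the machinery
under its own assumptions, not field performance on real cohorts.

## Preprocessing

Filtering keeps genes with ≥ `min_reads` (20) reads in ≥ `min_subjects`
(10) subjects; the operation is idempotent and reports retained/removed
counts. Normalization follows the published voom recipe, reimplemented
here: `values = log2((count + 0.5)/(lib + 1) × 10⁶)`; a lowess trend
(span 0.5) of √(gene residual sd) on average log2 count; per-observation
weights equal to the predicted √sd at the observation's fitted log-count,
raised to the −4 power (i.e. inverse predicted variance of the log2-CPM).
Duplicate trend abscissae are collapsed before interpolation, making the
weights invariant to gene order. No between-sample scale-factor (TMM-style)
normalization is applied.

The outlier screen flags subjects beyond `k_sd = 2` standard deviations on
either of two criteria: mean inter-subject Pearson correlation (one-sided —
only unusually *low* correlation marks an outlier) and PC1/PC2 scores
(two-sided). The two criteria are OR-combined. At n = 30 a 2-sd rule flags
a couple of borderline subjects by chance in clean data; the screen is a
report, not an automatic exclusion.

## Signed network and module detection

Adjacency is the signed soft threshold `((1 + r)/2)^β`, β = 9 (an unsigned
`|r|^β` option exists). Zero-variance genes are dropped with a warning
before correlation. The topological overlap matrix is

    TOM_ij = (Σ_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij),  i ≠ j

with `k_i = Σ_{j≠i} a_ij` and unit diagonal; clustering runs on `1 − TOM`
with average linkage. `scale_free_fit` reports the signed R² of the
log-frequency versus log-connectivity regression over 10 bins (negated for
positive slopes, NaN with a warning for degenerate networks); it is a
diagnostic, not an automatic β selector.

The hybrid tree cut is a simplified reimplementation, deliberately pinned
by block-structure and recovery tests rather than by equivalence to the
reference algorithm:

1. candidate cut heights (≤ 80 quantiles of the merge heights) are scanned
   and the cut producing the most *accepted* clusters wins. A cluster is
   accepted when it has ≥ `min_module_size` (15) genes and its mean
   internal dissimilarity is below `cohesion_ratio` (0.95) of the
   matrix-wide mean — the cohesion test rejects loose agglomerates of
   background genes that a pure size rule would admit;
2. ties between equally good cut heights are resolved by `deep_split`
   (0–4): deeper split prefers the finest (lowest) qualifying cut;
3. each accepted cluster is re-split at the widest relative gap of its own
   merge heights (gap threshold `0.40 − 0.075·deep_split` of the height
   range) when that yields ≥ 2 accepted sub-clusters;
4. remaining genes join the nearest module if their mean dissimilarity to
   it is < 0.8, otherwise they are grey (label 0). When no cluster is
   acceptable (e.g. all blocks below the minimum size) everything is grey.

Merging then clusters eigengenes on `1 − cor(ME)` and fuses modules joined
below `merge_cut_height` (0.2), recomputing eigengenes each round until no
pair of final eigengenes has correlation above `1 − merge_cut_height`.
Over-splitting in step 3 is self-healing here, since two halves of one true
module produce nearly identical eigengenes.

Eigengenes are the first right-singular vector of the standardized
(per-gene mean 0, sd 1) module submatrix — unit-norm across subjects,
sign-oriented so the majority of member genes correlate positively —
with variance explained `σ₁²/Σσ²`. kME is the plain Pearson correlation of
each gene with each eigengene; the hub gene maximizes own-module kME with
ties broken by gene id.

## Bayes-regularized ANOVA

For each feature and group, a background variance is the mean sample
variance of the `win_size` (5) features nearest in overall mean (window
clipped at the edges — relevant when the feature set is small, e.g. a few
dozen eigengenes; the clipping note is recorded in the output metadata).
The regularized within-group variance is

    s̃² = (conf · s²_bg + (n − 1) s²) / (conf + n − 1),

a Cyber-T-style shrinkage with `conf` (12) pseudo-observations. The
denominator uses `n − 1` rather than the original recipe's `n − 2` so that
`conf → 0` recovers the classical sample variance exactly; the omnibus F
(between-group mean square over pooled regularized variance, error df
`Σ(n_k − 1) + K·conf`) then reduces to classical one-way ANOVA in that
limit, which the tests assert to 10⁻⁶ and which keeps the null
false-positive rate calibrated (measured 0.042 at nominal 0.05). Pairwise
post hoc tests use the pooled regularized variance of the two groups; the
family-corrected p is the studentized-range (Tukey) tail probability,
floored at the raw p so corrected ≥ raw always holds. With `bayes` off the
procedure is classical one-way ANOVA plus Tukey HSD.

Module–trait association is pairwise-complete Pearson correlation with the
Student asymptotic two-sided p (`t = r√((n−2)/(1−r²))`, n − 2 df). Group
status is encoded as one-vs-rest 0/1 indicators. Raw p-values are reported
with the table-wide Bonferroni threshold alongside, mirroring how such
tables are read (nominal findings flagged against the conservative bar).
Constant traits are recorded as missing with a warning.

Gene-set enrichment is the upper-tail hypergeometric probability of the
observed-or-larger overlap; sets overlapping the query in fewer than 2
genes are skipped (not tested), and Bonferroni correction runs over the
sets actually tested.

## Moderated t and diagnostic panels

The moderated t-test estimates prior df d₀ and prior variance s₀² by
method of moments on the log sample variances (digamma/trigamma
identities; complete shrinkage when the observed spread does not exceed
the sampling spread), forms the posterior variance
`s̃²_g = (d₀s₀² + d_g s²_g)/(d₀ + d_g)` and refers
`t = Δmean/(s̃_g √(1/n_A + 1/n_B))` to t with d₀ + d_g df (normal when d₀
is infinite). `prior_df=0` reproduces the ordinary pooled t exactly.
Observation weights are not used in the test (a trend-moderated unweighted
analysis); the candidate screen is nominal p < 0.01.

Genes from modules whose eigengene correlates with any substance-use
covariate at raw p < 0.05 are excluded from candidate pools (confounder
exclusion), with a removal log.

DLDA scores a sample by `Σ_j (x_j − μ_kj)²/σ̂_j²` with the pooled
within-class diagonal variance and predicts the argmin class (ties to the
first class in sorted order; zero-variance genes dropped with a warning).
RFE under LOOCV: within every fold the candidates are re-ranked by
|moderated t| on the training subjects only — the held-out subject never
influences the ranking used to predict it — and nested panels along the
elimination path (drop the lowest 10 %, at least one gene, per step down
to a single gene) are evaluated for DLDA and the three comparators
(linear SVM with cost 1, unshrunken nearest centroid, 3-NN on Euclidean
distance). Because the ranking is a filter statistic, the elimination path
is exactly the nested top-k sets of that ranking. The best size maximizes
held-out accuracy with ties to the smallest panel; the reported panel is
refit on all subjects at that size, and per-gene CV support is the
percentage of folds whose selected panel contained the gene. The
controls-vs-METH model pools MA and MAP into one class; accuracy is
unweighted. Permutation p-values rerun the entire procedure (selection
inside the loop) on label permutations:
`p = (1 + #{perm error ≤ observed})/(n_perm + 1)`.

Note that the *best-over-panel-sizes* accuracy is an optimistically biased
summary under the null (≈ 0.6–0.7 rather than 0.5 for 20 balanced
subjects); the permutation p-value is computed against exactly the same
maximization and is therefore the honest significance measure.

## CFG scoring

Internal: per comparison 1 point if p < 0.001, 0.5 if 0.001 ≤ p < 0.01,
0.2 if 0.01 ≤ p < 0.05 (boundaries fall in the lower-scoring bin — the
only consistent reading of the interval rules); +0.5 when both MAP
comparisons pass p < 0.01; +0.5 for membership in a MAP-associated module
(modules whose eigengene group test is significant for a MAP contrast,
passed in explicitly so the scorer stays pure). A gene is included only if
at least one comparison has p < 0.05, so the included range is [0.2, 4].

External: one line of evidence per distinct (evidence type × disease)
combination regardless of publication multiplicity, 1 point each, capped
at 5; a (blood_expression, psychosis) line adds 1 extra point outside the
cap, making the maximum total 10 = 4 + 5 + 1. Records flagged as
methamphetamine studies are excluded before scoring, as are records with
unknown types or diseases (counted and reported). The prioritization
threshold defaults to 3 and is configurable (a threshold of 2 is the other
defensible published convention; neither is privileged by the code).
Module-level CFG enrichment reuses the hypergeometric machinery against
the expressed background.

## Orchestration and reproducibility

`run_pipeline` chains simulate → preprocess → network → module statistics
→ DE/classifier → CFG, persisting every intermediate artifact as TSV/JSON
and emitting a run report (configs, seeds, stage timings, headline
outputs). A single global seed derives per-stage seeds by fixed offsets,
so identical configuration and seed give identical reports up to timings;
this is asserted by tests. Classifier permutations default to off in the
pipeline (set `n_permutations`) because they multiply the RFE cost by the
permutation count; `permutation_pvalue` is available directly.

## Problem sizes used by the test suite

Unit and property tests run on toy matrices (≤ 50 genes). Recovery tests
use the default 2000-gene cohort (one seed); calibration tests use
1000-feature nulls over 10 seeds, and the end-to-end null experiment uses
20 seeds of an 800-gene, 4-module null cohort with the classifier stage
disabled. These sizes keep the full suite around one minute on one CPU
while leaving every statistical conclusion at its stated confidence.

## Known limitations

* The tree cut is behavior-pinned, not a numerical clone of the reference
  hybrid dynamic tree cut; partitions on real data will differ in detail.
* The voom reimplementation uses the overall (design-free) gene variance
  for the trend rather than residuals from a group-means fit; on balanced
  three-group designs with modest effects the difference is small.
* Best-size selection inside LOOCV is reported per classifier without a
  nested outer validation; the permutation test is the guard against
  optimism.
* At n = 10 per group, trait correlations and post hoc contrasts are
  screening statistics; the package reports raw and corrected values and
  leaves inference discipline to the user.
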