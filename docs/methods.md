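# Methods

## Scope and data model

The package operates downstream of read processing: its inputs are an
ASV count table (samples × taxa, non-negative integers), a rooted
phylogeny with branch lengths whose leaves cover the table's taxa, and
per-sample metadata with a `site` label ordered along the migration
axis (rural < urban < amsterdam), cardiometabolic covariates and an
antibiotic-use flag. Count tables are plain pandas DataFrames; trees
are `skbio.TreeNode`. On disk, tables are TSV or minimal BIOM v1 JSON
(a hand-rolled codec — BIOM v1 is plain JSON — cross-checked against
the TSV codec), trees are Newick, metadata is TSV.

## Preprocessing

Samples are excluded when their total count falls below the rarefaction
depth or when the antibiotic flag is set; a sample failing both is
counted once under low-count (first-listed reason). Rarefaction draws
each sample's retained reads **without replacement** (one multivariate
hypergeometric draw per sample), so support is conserved: a taxon
absent before rarefaction stays absent. Samples below depth are
excluded, never resampled. Abundance filtering keeps ASVs with
≥ `min_count` (default 10) counts in ≥ ⌈`min_frac`·n⌉ samples (default
30 %); prevalence filtering keeps ASVs present in ≥ ⌈`min_prev`·n⌉
samples (default 10 %). All thresholds are boundary-inclusive. The
log-abundance transform is log₁₀(count + 1): zeros map to zero and
order is preserved; it is applied to rarefied counts so depths are
comparable.

## Diversity

Shannon entropy uses the natural log (configurable downstream by
rescaling). Faith's PD is root-inclusive: the sum of branch lengths on
all root-to-present-leaf paths, so even a single present leaf has
positive PD. Weighted UniFrac is the normalized variant
Σ l_b|A_b − B_b| / Σ l_b(A_b + B_b); the unnormalized numerator is
available via `normalized=False`. Both are computed from a branch
incidence table (branch length + descendant leaf set per edge) built in
one postorder pass; the all-pairs routine reuses one branch-fraction
matrix per cohort. PERMANOVA uses Anderson's construction on squared
distances: SS_total = Σ_{i<j} d²/N, within-group sums weighted by group
size, pseudo-F = (SS_among/(k−1))/(SS_within/(N−k)), and
p = (1 + #{F_perm ≥ F_obs})/(n_perm + 1) under whole-label
permutations (default 999, seed recorded), so the attainable minimum is
1/(n_perm+1).

## Prediction scaffold

Each outer iteration i derives its seed from (global seed, i) via
`numpy.random.SeedSequence`, so runs are reproducible and iterations
independent. Within an iteration: benchmark features are regenerated
(one uniform, one fair coin for the default n = 2); the data is split
80/20 (stratified for classification; in the rare unstratifiable case
the split is redrawn until both classes reach the test set, with a
logged counter); the hyperparameter grid is scored by 5-fold CV inside
the training set only (an audit assertion verifies inner folds never
intersect the test indices); the best configuration — ties resolved by
grid order — is refit on the full training set and evaluated once.
The inner selection metric equals the outer metric. The default grid
(tree depth {3,5,7}, learning rate {0.05,0.1}, ensemble size {100,300},
subsample {0.7,1.0}) is a desk-scale choice and fully overridable;
`SMALL_GRID` (one combination) serves quick runs. Importances are total
split gain normalized to sum 1 per iteration; features are ranked by
mean importance with lexicographic tie-breaks. The permuted-label
control permutes the outcome once per iteration before splitting and is
otherwise identical. Under a true null the mean test AUC sits near 0.5
(gradient boosting on pure noise can drift slightly below chance on
held-out data; the effect is within the chance band at 25 iterations).

## Site associations

The diet PCA z-scores five macronutrient variables (protein, fat,
carbohydrates, fibre, sodium — configurable; cohort metadata tables
vary in how many diet variables they carry) and extracts two components
from the correlation structure via SVD, with a deterministic sign
convention (largest-magnitude loading positive). The PCA is fit on the
full cohort, not per site pair. Regressions code the second-listed
site of each pair as 1, so positive betas mean higher abundance further
along the migration axis; tiers add (2) age, sex, BMI, hypertension and
(3) diet PC1/PC2. Missing covariate rows are dropped per tier and
counted. BH-FDR is applied within one (site pair × tier) family.
Collinear designs raise, naming a removable column set.

## Vanish / blossum

Predictors are the deduplicated union (first-seen order) of the two
pairwise presence-absence classifiers' top-10 features. Direction uses
the axis endpoints: vanish iff prevalence(amsterdam) <
prevalence(rural), blossum iff greater; exact endpoint ties are flagged
indeterminate and excluded with a warning, the urban prevalence being
reported but not decisive. Group thresholds default to "≥ 10 of 13
vanish taxa absent" and "≥ 4 of 6 blossum taxa present" and are
configurable; on synthetic cohorts with 5 + 4 planted taxa the tests
use the proportionally scaled 4/5 and 3/4. The outcome panel uses
Mann-Whitney for continuous and chi-square (no continuity correction)
for binary variables, with a Fisher-exact fallback when an expected
cell is zero. Obesity is defined as BMI ≥ 30 kg/m² and
hypercholesterolemia as total cholesterol > 5.0 mmol/L when those flags
are not supplied.

## Synthetic cohort generator

The generator defines the study conditions for all recovery tests; it
emulates a three-site West-African migration cohort, not any particular
dataset's noise structure.

* **Composition.** Taxon log relative abundances are normal (sd 1.5
  background); per-sample, per-taxon log-normal noise (sd 0.6)
  supplies overdispersion; counts are one multinomial draw per sample
  at a depth uniform on [depth, 2·depth] with depth = rarefaction depth
  (default 2 000 — desk-scale; configurable).
* **Gradient taxa** (default 10) start at a high baseline (log-mean
  2.0, sd 0.3, so counts stay well above zero at the low end) and shift
  by `effect_size` (default 1.0 ln-units ≈ 2.7-fold) per site step with
  alternating sign, keeping total composition roughly balanced.
* **Vanish/blossum taxa** (defaults 5 and 4) are present per sample
  with Bernoulli probability (0.9, 0.5, 0.1) and (0.1, 0.5, 0.9) along
  the axis; absent means zero expected abundance.
* **Covariates** are drawn per site with means and spreads realistic
  for a rural/urban/European migration cohort (e.g. BMI 23.0/28.3/29.2
  kg/m², protein 68/76/97 g/d, HbA1c 33/42/40 mmol/mol); hypertension,
  diabetes and sex are Bernoulli; physical activity is log-normal.
  Protein and sodium are linked to specific gradient taxa
  (0.25 log-units per covariate SD), so diet genuinely mediates part of
  the site effect and staged adjustment has something to attenuate.
* **Planted truth.** Besides roles and profiles, the truth records each
  gradient taxon's expected log₁₀(count + 1) shift per site pair,
  computed from the generative model itself: Gauss–Hermite integration
  over the log-normal noise of the exact Poisson expectation
  E[log₁₀(N+1)] at the rarefied depth, with the compositional
  normalizer approximated by its expectation. This puts the truth on
  exactly the scale the tier-1 regressions estimate, including
  pseudocount and zero-truncation effects at low abundance.
* One global seed spawns per-component seed sequences (tree, metadata,
  counts), so components are independently reproducible and identical
  configs yield bit-identical cohorts.

What the generator does **not** emulate: real phylogenetic signal in
abundances (the tree is random-join with exponential branch lengths),
taxonomy-assignment error, batch effects, read-level noise, or the long
compositional tail of real 16S data. Passing recovery tests therefore
demonstrates correctness of the estimators under the stated model, not
field performance on real cohorts.

## Problem sizes and numerical choices

Tests and the acceptance script run at reduced sizes chosen as the
package's own desk-scale conditions: 100–150 samples per site, 120
taxa, depth 2 000, 15–25 outer CV iterations with the one-combination
grid, 10–15 generator replicates for regression recovery, 200
PERMANOVA null replicates at 99 permutations. Larger runs are purely a
matter of configuration. Degenerate inputs fail loudly: all-zero
samples for Shannon/UniFrac, sub-depth samples at rarefaction,
single-class test draws (redrawn with a counter), constant outcomes,
zero-variance PCA variables, collinear designs, thresholds exceeding
predictor-set sizes. Pipeline reports are written with a fixed float
format so identical configurations reproduce byte-identical outputs.

## Known limitations

* The PERMANOVA permutation loop is O(n_perm · N²) in pure
  numpy — fine to a few thousand samples, not optimized beyond that.
* The CLI's stage subcommands recompute upstream stages in memory
  (they are cheap and deterministic) rather than reading intermediate
  files.
* The learner contract is any sklearn-style tree ensemble exposing
  split-gain importances; only the XGBoost default is exercised in the
  test suite.
* Presence-absence analyses inherit rarefaction's stochastic zeros at
  low abundance; prevalence targets are therefore verified against
  binomial bounds on the Bernoulli presence draws, with multinomial
  sampling adding a small downward bias at very low planted abundance.
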