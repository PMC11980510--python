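# gutshift

Analysis of gut-microbiota shifts along a rural → urban → migration axis,
for microbiome researchers studying how urbanization and international
migration reshape the gut ecosystem and its links to cardiometabolic
health. Starting from an ASV count table (samples × amplicon sequence
variants), a rooted phylogeny and sample metadata from a multi-site
cohort, the package reproduces a complete migration-axis analysis:

1. **Preprocessing** — exclusion of low-depth and antibiotic-exposed
   samples, rarefaction without replacement to a common depth,
   abundance filtering (≥ 10 counts in ≥ 30 % of samples) and
   prevalence filtering (present in ≥ 10 % of samples).
2. **Diversity** — Shannon entropy *H = −Σ pᵢ ln pᵢ*, richness, Faith's
   phylogenetic diversity (total branch length spanned by the present
   taxa, root-inclusive), normalized weighted UniFrac
   *d(u,v) = Σ_b l_b |A_b − B_b| / Σ_b l_b (A_b + B_b)* over branches
   *b* with length *l_b* and descendant abundance fractions *A_b*,
   *B_b*, and PERMANOVA (Anderson's pseudo-F with whole-label
   permutations).
3. **Prediction scaffold** — pairwise site classification (and
   covariate regression) with gradient-boosted trees in a nested
   cross-validation design: 200 outer iterations of a stratified 80/20
   split, 5-fold inner grid search, one evaluation per iteration on the
   untouched test set; two injected random benchmark features and a
   permuted-label control guard against overfitting. Metrics: AUC for
   classification, explained variance (1 − SS_res/SS_tot) for
   regression; importances are normalized total split gain.
4. **Site associations** — per top-ranked ASV, OLS of log₁₀(count + 1)
   on a binary site indicator in three tiers (unadjusted; + age, sex,
   BMI, hypertension; + the first two principal components of
   macronutrient intake), with Benjamini–Hochberg q-values.
5. **Vanish / blossum statistics** — taxa whose prevalence falls
   (vanish) or rises (blossum) from the rural to the migration endpoint
   are selected from the union of the two pairwise presence-absence
   classifiers' top-10 rankings; samples lacking ≥ 10 of 13 vanish taxa
   (or carrying ≥ 4 of 6 blossum taxa) form groups that are compared on
   cardiometabolic outcomes with Mann-Whitney and chi-square tests.

A bundled synthetic-cohort generator emulates the three-site study
design (474/460/243 participants by default) with planted gradient
taxa, planted prevalence-shift taxa and site-correlated covariates, so
every stage is testable against a known ground truth.

## Worked example

Run the full pipeline on a simulated 150-sample cohort:

```python
from gutshift.pipeline import RunConfig, run_pipeline

cfg = RunConfig(
    simulate={"n_per_site": [50, 50, 50], "n_taxa": 80},
    depth=2000,
    ml={"n_iterations": 5, "hyperparameter_grid": {
        "max_depth": [3], "learning_rate": [0.1],
        "n_estimators": [100], "subsample": [1.0]}},
    vanish_min_absent=4, blossum_min_present=3,
    n_permutations=999, seed=17)
bundle = run_pipeline(cfg, "out/")
print(bundle["permanova"])
print(bundle["ml_metrics"])
```

which prints (alpha diversity falls along the axis, sites separate in
beta diversity, and the classifiers find the planted signal while their
permuted-label controls stay at chance):

```
site       shannon  richness  faith_pd
rural         3.42     67.66     14.15
urban         3.13     65.22     13.84
amsterdam     2.68     60.54     13.25

 pseudo_f  r_squared  p_value  n_permutations
62.368426   0.459035    0.001             999

      site_pair      route   mean  permuted_mean
    rural-urban  abundance  0.996          0.568
    rural-urban prevalence  0.934          0.468
urban-amsterdam  abundance  0.990          0.564
urban-amsterdam prevalence  0.952          0.572
```

The vanish group (99 of 150 samples lacking ≥ 4 of the selected
disappearing taxa) shows the planted higher BMI
(Mann-Whitney p = 8 × 10⁻⁶) and higher HbA1c (p = 0.046) relative to
controls. The same run is available from the shell:

```sh
gutshift simulate --seed 17 --out sim/
gutshift run-all --config run.yaml --out out/
```

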